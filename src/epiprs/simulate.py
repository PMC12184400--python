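"""Regulatory phenotype simulation on synthetic phased cohorts.

Binary traits are generated from a four-component liability model

    g(mu_i) = alpha0 + y_epi_i + y_direct_i + y_env_i + y_inter_i

where the epigenetic component sums, over causal genes g, expressed
transcription factors t and causal regulatory variants k in S_g, the
products X_ik * B_tk * e_gtk of normalized genotype, binary TF-binding
indicator, and a per-(TF, variant) random effect e_gtk ~ N(0, sigma_t^2)
with sigma_t^2 ~ InvGamma(shape=3, scale=1).  The direct component is a
weighted sum of normalized dosages over SNPs outside all causal-gene
regulatory elements with N(0,1) weights; the interaction component is a
weighted sum of products of disjoint random pairs of causal genotypes;
the environmental component is independent Gaussian noise.  Each genetic
component is affinely rescaled to population mean 0 and variance exactly
equal to its configured proportion (h_epi^2, h_direct^2, h_inter^2), and
the environmental variance targets the remainder, so total liability
variance is ~1.  Case/control labels come either from thresholding the
liability so the case count is exactly round(n * prevalence), or from a
Bernoulli draw with a logit link whose intercept alpha0 is solved so the
expected case fraction equals the prevalence.

Genotypes are drawn per site from a configurable minor-allele-frequency
spectrum: a controllable fraction of causal variants is rare
(MAF in [0.001, 0.01) by default), the rest common (MAF in [0.05, 0.5]),
which is the dial behind rare-variant-architecture benchmarking.

In *sequence-coupled* mode the simulator additionally emits a reference
sequence in which every causal variant sits inside a planted consensus
motif of its binding TF, drawn from the synthetic feature extractor's
motif set, and the alternate allele destroys the motif match.  Causal
alleles then genuinely change the extractor's motif-count features,
closing the chain genotype -> sequence -> feature -> phenotype.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from epiprs.genome import PhasedVariants
from epiprs.windows import LDBlock, WindowConfig

__all__ = [
    "SimConfig",
    "Cohort",
    "AnnotationSet",
    "EffectDraws",
    "LiabilityComponents",
    "SimDataset",
    "simulate_cohort",
    "normalize_genotypes",
    "build_annotations",
    "draw_effects",
    "compute_liability",
    "assign_phenotypes",
    "simulate_dataset",
    "run_replicates",
    "child_seed",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one simulated cohort.

    Variance proportions ``h_epi2 + h_direct2 + h_inter2`` must not
    exceed 1; the environmental variance is the remainder.  Defaults:
    prevalence 0.5, one causal gene per LD block, 100 causal variants
    per causal gene, rare MAF in [0.001, 0.01), common MAF in
    [0.05, 0.5], threshold-mode phenotypes.
    """

    n: int = 4000
    m: int = 2000
    h_epi2: float = 0.5
    h_direct2: float = 0.3
    h_inter2: float = 0.0
    prevalence: float = 0.5
    rare_fraction: float = 0.0
    rare_maf: tuple[float, float] = (0.001, 0.01)
    common_maf: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 1
    causal_genes_per_block: int = 1
    causal_per_gene: int = 100
    f_inter: float = 0.0
    n_tfs: int = 8
    tf_hit_prob: float = 0.3
    phenotype_mode: str = "threshold"
    ld_rho: float = 0.0
    site_spacing: int = 16
    block_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h_epi2 <= 1 and 0 <= self.h_direct2 <= 1 and 0 <= self.h_inter2 <= 1):
            raise ValueError("variance proportions must lie in [0, 1]")
        if self.h_epi2 + self.h_direct2 + self.h_inter2 > 1 + 1e-12:
            raise ValueError("h_epi2 + h_direct2 + h_inter2 must be <= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.rare_fraction <= 1:
            raise ValueError("rare_fraction must be in [0, 1]")
        for (lo, hi), nm in ((self.rare_maf, "rare"), (self.common_maf, "common")):
            if not (0 < lo < hi <= 0.5):
                raise ValueError(f"{nm} MAF range must satisfy 0 < lo < hi <= 0.5")
        if self.rare_maf[1] > self.common_maf[0]:
            raise ValueError("rare and common MAF ranges must be disjoint")
        if self.phenotype_mode not in ("threshold", "bernoulli"):
            raise ValueError(f"unknown phenotype mode {self.phenotype_mode!r}")
        if self.m % self.n_blocks != 0:
            raise ValueError("m must divide evenly across blocks")

    @property
    def m_per_block(self) -> int:
        return self.m // self.n_blocks

    @property
    def n_causal(self) -> int:
        return self.n_blocks * self.causal_genes_per_block * self.causal_per_gene

    @property
    def h_env2(self) -> float:
        return max(0.0, 1.0 - self.h_epi2 - self.h_direct2 - self.h_inter2)


def child_seed(master: int, *tags) -> int:
    """Deterministic named child seed below 2**31 (stable across processes)."""
    digest = hashlib.sha256(
        ("|".join([str(int(master))] + [str(t) for t in tags])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


@dataclass
class Cohort:
    """Synthetic phased cohort plus the causal layout it was drawn under."""

    variants: PhasedVariants
    maf: np.ndarray  # drawn (target) MAF per site
    blocks: list[LDBlock]
    block_of_site: np.ndarray  # block index per site
    causal_sites: np.ndarray  # site indices, all blocks pooled
    rare_causal: np.ndarray  # bool over causal_sites
    gene_anchors: np.ndarray  # one position per block (0-based)
    cfg: SimConfig

    @property
    def n(self) -> int:
        return self.variants.n_samples

    @property
    def m(self) -> int:
        return self.variants.n_sites

    def dosages(self) -> np.ndarray:
        return self.variants.dosages()


@dataclass
class AnnotationSet:
    """Causal genes, regulatory elements and TF binding for a cohort.

    ``binding`` is the binary (n_tfs, m) matrix B: B[t, k] = 1 iff
    variant k overlaps a binding site of TF t.  ``re_intervals`` holds
    (chrom, start, end) regulatory elements; every causal variant lies
    inside one, every non-causal variant outside all.
    """

    causal_sites: np.ndarray
    causal_gene_of_site: np.ndarray  # gene index per causal site
    binding: np.ndarray
    re_intervals: list[tuple[str, int, int]]
    non_re_sites: np.ndarray
    tf_of_causal: np.ndarray | None = None  # coupled mode: one TF per causal site


@dataclass
class EffectDraws:
    """Random effect draws of the liability model, reproducible from seed."""

    sigma2_t: np.ndarray  # (n_tfs,), InvGamma(3, 1)
    e_tk: np.ndarray  # (n_tfs, m); used where binding & causal
    beta: np.ndarray  # (m,), N(0, 1); used on non-RE sites
    inter_pairs: np.ndarray  # (n_pairs, 2) site indices, disjoint
    gamma: np.ndarray  # (n_pairs,), N(0, 1)


@dataclass
class LiabilityComponents:
    """The four liability components, the intercept and the labels."""

    y_epi: np.ndarray
    y_direct: np.ndarray
    y_env: np.ndarray
    y_inter: np.ndarray
    alpha0: float | None = None
    mu: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def liability(self) -> np.ndarray:
        return self.y_epi + self.y_direct + self.y_env + self.y_inter


def _draw_site_haplotypes(rng: np.random.Generator, n: int, maf: np.ndarray, rho: float) -> np.ndarray:
    """(m, n, 2) alleles; per-haplotype AR(1) latent Gaussian when rho>0."""
    m = maf.size
    if rho == 0.0:
        return (rng.random((m, n, 2)) < maf[:, None, None]).astype(np.int8)
    z = np.empty((m, n, 2))
    z[0] = rng.standard_normal((n, 2))
    innov = rng.standard_normal((m - 1, n, 2)) * np.sqrt(1 - rho**2)
    for j in range(1, m):
        z[j] = rho * z[j - 1] + innov[j - 1]
    thresh = stats.norm.ppf(maf)[:, None, None]
    return (z < thresh).astype(np.int8)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Draw a phased cohort under the configured MAF spectrum.

    Sites are laid on a minimum-spacing grid within each block (one
    block per synthetic contig).  Causal sites — ``causal_per_gene`` per
    causal gene, one gene anchor per block — are chosen first and
    exactly ``round(rare_fraction * n_causal)`` of them receive a
    rare-range MAF; all remaining sites are common.  Haplotype alleles
    are Bernoulli(MAF) per haplotype (optionally correlated along the
    block through a latent AR(1) Gaussian, ``ld_rho``).  Monomorphic
    sites are redrawn; persistent monomorphism raises with a suggestion
    to increase n.
    """
    rng_layout = np.random.default_rng(child_seed(cfg.seed, "layout"))
    rng_geno = np.random.default_rng(child_seed(cfg.seed, "genotypes"))

    mpb = cfg.m_per_block
    n_causal_pb = cfg.causal_genes_per_block * cfg.causal_per_gene
    if n_causal_pb > mpb:
        raise ValueError(
            f"{n_causal_pb} causal variants per block requested but only "
            f"{mpb} sites per block"
        )
    block_len = cfg.block_length or max(2048, mpb * cfg.site_spacing)
    n_slots = block_len // cfg.site_spacing
    if n_slots < mpb:
        raise ValueError("block_length too short for m sites at the minimum spacing")

    positions, chroms, block_idx = [], [], []
    causal_sites, gene_anchors = [], []
    block_start = block_len  # margin on each side of the block within its contig
    blocks = []
    for b in range(cfg.n_blocks):
        name = f"blk{b}"
        slots = np.sort(rng_layout.choice(n_slots, size=mpb, replace=False))
        pos = block_start + slots * cfg.site_spacing + cfg.site_spacing // 2
        positions.append(pos)
        chroms.extend([name] * mpb)
        block_idx.extend([b] * mpb)
        blocks.append(LDBlock(id=name, chrom=name, start=block_start, end=block_start + block_len))
        causal_local = np.sort(rng_layout.choice(mpb, size=n_causal_pb, replace=False))
        causal_sites.append(causal_local + b * mpb)
        gene_anchors.append(int(rng_layout.integers(block_start, block_start + block_len)))

    pos_all = np.concatenate(positions)
    causal_all = np.concatenate(causal_sites)

    # MAF spectrum: exact rare count among causal sites, common elsewhere
    maf = rng_layout.uniform(*cfg.common_maf, size=cfg.m)
    n_rare = int(round(cfg.rare_fraction * causal_all.size))
    rare_mask_c = np.zeros(causal_all.size, dtype=bool)
    rare_mask_c[rng_layout.choice(causal_all.size, size=n_rare, replace=False)] = True
    maf[causal_all[rare_mask_c]] = rng_layout.uniform(*cfg.rare_maf, size=n_rare)
    maf[causal_all[~rare_mask_c]] = rng_layout.uniform(
        *cfg.common_maf, size=int((~rare_mask_c).sum())
    )

    haps = _draw_site_haplotypes(rng_geno, cfg.n, maf, cfg.ld_rho)
    counts = haps.sum(axis=(1, 2))
    for k in np.nonzero((counts == 0) | (counts == 2 * cfg.n))[0]:
        for attempt in range(100):
            col = (rng_geno.random((cfg.n, 2)) < maf[k]).astype(np.int8)
            c = int(col.sum())
            if 0 < c < 2 * cfg.n:
                haps[k] = col
                break
        else:
            raise ValueError(
                f"site {k} (MAF {maf[k]:.4g}) stayed monomorphic after 100 "
                f"redraws; increase n"
            )

    samples = [f"S{i:05d}" for i in range(cfg.n)]
    # placeholder alleles; sequence-coupled reference construction overwrites
    ref = np.array(list("ACGT"))[rng_layout.integers(0, 4, size=cfg.m)]
    shift = rng_layout.integers(1, 4, size=cfg.m)
    alt = np.array(list("ACGT"))[
        (np.searchsorted(np.array(list("ACGT")), ref) + shift) % 4
    ]
    variants = PhasedVariants(
        samples=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=pos_all,
        ref=ref.astype(object),
        alt=alt.astype(object),
        haplotypes=haps,
    )
    return Cohort(
        variants=variants,
        maf=maf,
        blocks=blocks,
        block_of_site=np.asarray(block_idx),
        causal_sites=causal_all,
        rare_causal=rare_mask_c,
        gene_anchors=np.asarray(gene_anchors),
        cfg=cfg,
    )


def normalize_genotypes(cohort: Cohort | np.ndarray) -> np.ndarray:
    """Per-site standardized dosage matrix X (n x m): mean 0, variance 1."""
    d = cohort.dosages() if isinstance(cohort, Cohort) else np.asarray(cohort)
    d = d.astype(np.float64)
    mean = d.mean(axis=0)
    sd = d.std(axis=0)
    if np.any(sd == 0):
        k = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"site {k} is monomorphic (zero dosage variance)")
    return (d - mean) / sd


def build_annotations(
    cohort: Cohort, seed: int | None = None, sequence_coupled: bool = False
) -> AnnotationSet:
    """Derive the regulatory annotation set from the cohort's causal layout.

    Regulatory-element intervals are placed around the causal variants
    of each block's causal gene (all within 1 Mb of the gene anchor at
    desk scale), so every causal site overlaps an RE and every other
    site is RE-free.  The binary binding matrix B assigns TFs to causal
    sites: independently with probability ``tf_hit_prob`` per TF
    (generic mode), or exactly one uniformly drawn TF per causal site
    (sequence-coupled mode, where that TF's consensus motif is planted
    in the reference around the site).  A TF left with no binding site
    is given one so every TF can contribute to the epigenetic effect.
    """
    cfg = cohort.cfg
    rng = np.random.default_rng(
        child_seed(cfg.seed, "annotations") if seed is None else seed
    )
    causal = cohort.causal_sites
    nc = causal.size

    re_halfwidth = min(10, (cfg.site_spacing - 1) // 2)
    re_intervals = [
        (str(cohort.variants.chrom[k]), int(cohort.variants.pos[k]) - re_halfwidth,
         int(cohort.variants.pos[k]) + re_halfwidth + 1)
        for k in causal
    ]
    non_re = np.setdiff1d(np.arange(cohort.m), causal)

    B = np.zeros((cfg.n_tfs, cohort.m), dtype=np.int8)
    tf_of_causal = None
    if sequence_coupled:
        tf_of_causal = rng.integers(0, cfg.n_tfs, size=nc)
        B[tf_of_causal, causal] = 1
    else:
        hits = rng.random((cfg.n_tfs, nc)) < cfg.tf_hit_prob
        B[:, causal] = hits.astype(np.int8)
    for t in range(cfg.n_tfs):
        if B[t].sum() == 0:
            B[t, causal[rng.integers(0, nc)]] = 1

    gene_of = cohort.block_of_site[causal] * cfg.causal_genes_per_block
    return AnnotationSet(
        causal_sites=causal,
        causal_gene_of_site=gene_of,
        binding=B,
        re_intervals=re_intervals,
        non_re_sites=non_re,
        tf_of_causal=tf_of_causal,
    )


def draw_effects(cohort: Cohort, ann: AnnotationSet, seed: int | None = None) -> EffectDraws:
    """Draw all random effects of the liability model.

    sigma_t^2 ~ InvGamma(shape 3, scale 1); e_tk ~ N(0, sigma_t^2);
    beta_k ~ N(0, 1); interaction pairs are disjoint random pairs of
    causal sites, round(f_inter * n_causal / 2) of them, with N(0, 1)
    coefficients.
    """
    cfg = cohort.cfg
    rng = np.random.default_rng(
        child_seed(cfg.seed, "effects") if seed is None else seed
    )
    sigma2 = stats.invgamma.rvs(a=3.0, scale=1.0, size=cfg.n_tfs, random_state=rng)
    e_tk = rng.standard_normal((cfg.n_tfs, cohort.m)) * np.sqrt(sigma2)[:, None]
    beta = rng.standard_normal(cohort.m)

    n_pairs = int(round(cfg.f_inter * ann.causal_sites.size / 2))
    perm = rng.permutation(ann.causal_sites)
    pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2) if n_pairs else np.empty((0, 2), dtype=np.int64)
    gamma = rng.standard_normal(n_pairs)
    return EffectDraws(sigma2_t=sigma2, e_tk=e_tk, beta=beta, inter_pairs=pairs, gamma=gamma)


def _rescale(raw: np.ndarray, target_var: float, name: str) -> np.ndarray:
    if target_var == 0.0:
        return np.zeros_like(raw)
    sd = raw.std()
    if sd == 0:
        raise ValueError(
            f"{name} component is constant across individuals but its target "
            f"variance is {target_var}; degenerate annotation/effect draw"
        )
    return (raw - raw.mean()) / sd * np.sqrt(target_var)


def compute_liability(
    X: np.ndarray, ann: AnnotationSet, draws: EffectDraws, cfg: SimConfig,
    seed: int | None = None,
) -> LiabilityComponents:
    """Assemble the four liability components with exact variance calibration.

    Each genetic component is affinely rescaled to population mean 0 and
    variance exactly equal to its configured proportion; the
    environmental component is drawn N(0, 1 - h_epi2 - h_direct2 -
    h_inter2).  A raw genetic component that is constant while its
    target variance is positive raises.
    """
    rng = np.random.default_rng(child_seed(cfg.seed, "env") if seed is None else seed)
    causal = ann.causal_sites

    w = (ann.binding[:, causal] * draws.e_tk[:, causal]).sum(axis=0)
    raw_epi = X[:, causal] @ w
    y_epi = _rescale(raw_epi, cfg.h_epi2, "epigenetic")

    raw_direct = X[:, ann.non_re_sites] @ draws.beta[ann.non_re_sites]
    y_direct = _rescale(raw_direct, cfg.h_direct2, "direct")

    if draws.inter_pairs.size and cfg.h_inter2 > 0:
        prods = X[:, draws.inter_pairs[:, 0]] * X[:, draws.inter_pairs[:, 1]]
        raw_inter = prods @ draws.gamma
        y_inter = _rescale(raw_inter, cfg.h_inter2, "interaction")
    elif cfg.h_inter2 > 0:
        raise ValueError(
            "h_inter2 > 0 but no interaction pairs were drawn; set f_inter > 0"
        )
    else:
        y_inter = np.zeros(X.shape[0])

    env_var = cfg.h_env2
    y_env = (
        rng.standard_normal(X.shape[0]) * np.sqrt(env_var)
        if env_var > 0
        else np.zeros(X.shape[0])
    )
    return LiabilityComponents(y_epi=y_epi, y_direct=y_direct, y_env=y_env, y_inter=y_inter)


def assign_phenotypes(
    components: LiabilityComponents, cfg: SimConfig, seed: int | None = None
) -> LiabilityComponents:
    """Turn liabilities into case/control labels.

    Threshold mode (default): the round(n * prevalence) largest
    liabilities are cases, ties broken by a seeded random order; alpha0
    is reported as the implied cut point.  Bernoulli mode: alpha0 is
    solved by monotone root finding so mean(sigmoid(alpha0 + eta)) equals
    the prevalence to 1e-8, then labels are Bernoulli(mu).
    """
    rng = np.random.default_rng(
        child_seed(cfg.seed, "phenotype") if seed is None else seed
    )
    eta = components.liability
    n = eta.size
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite liabilities")

    if cfg.phenotype_mode == "threshold":
        n_cases = int(round(n * cfg.prevalence))
        tiebreak = rng.permutation(n)
        order = np.lexsort((tiebreak, -eta))
        labels = np.zeros(n, dtype=np.int8)
        labels[order[:n_cases]] = 1
        if 0 < n_cases < n:
            cut = (eta[order[n_cases - 1]] + eta[order[n_cases]]) / 2.0
        else:
            cut = float(eta.min() if n_cases == n else eta.max())
        components.alpha0 = float(cut)
        components.labels = labels
        components.mu = None
        return components

    def excess(a: float) -> float:
        return special.expit(a + eta).mean() - cfg.prevalence

    try:
        alpha0 = optimize.brentq(excess, -60.0, 60.0, xtol=1e-12, maxiter=200)
    except (ValueError, RuntimeError) as err:
        raise RuntimeError(
            f"prevalence root finding failed: f(-60)={excess(-60.0):.3g}, "
            f"f(60)={excess(60.0):.3g}"
        ) from err
    mu = special.expit(alpha0 + eta)
    components.alpha0 = float(alpha0)
    components.mu = mu
    components.labels = (rng.random(n) < mu).astype(np.int8)
    return components


@dataclass
class SimDataset:
    """A fully simulated study: cohort, annotations, effects, phenotypes.

    ``contigs`` maps contig name -> reference sequence (present when the
    dataset was built with a window geometry, e.g. in sequence-coupled
    mode); variant ref/alt alleles are consistent with it.
    """

    cfg: SimConfig
    cohort: Cohort
    annotations: AnnotationSet
    draws: EffectDraws
    components: LiabilityComponents
    contigs: dict[str, str] | None = None
    window_cfg: WindowConfig | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.components.labels

    @property
    def samples(self) -> list[str]:
        return self.cohort.variants.samples


def _build_reference(
    cohort: Cohort,
    ann: AnnotationSet,
    window_cfg: WindowConfig,
    extractor=None,
    seed: int | None = None,
) -> dict[str, str]:
    """Random reference contigs, with causal-site motif planting when coupled.

    Each block's contig is long enough that every tiled window's input
    interval stays on the contig.  In sequence-coupled mode the binding
    TF's consensus motif is written into the reference centred on each
    causal site, the reference allele is the motif base at the site, and
    the alternate allele is a different base — so the alternate allele
    breaks the exact motif match the extractor counts.
    """
    cfg = cohort.cfg
    rng = np.random.default_rng(
        child_seed(cfg.seed, "reference") if seed is None else seed
    )
    bases = np.array(list("ACGT"))
    contigs: dict[str, np.ndarray] = {}
    for blk in cohort.blocks:
        contig_len = blk.end + blk.start  # symmetric margin around the block
        contig_len = max(contig_len, window_cfg.input_length + 2 * window_cfg.flank)
        contigs[blk.chrom] = bases[rng.integers(0, 4, size=contig_len)].copy()

    ref = cohort.variants.ref
    alt = cohort.variants.alt
    pos = cohort.variants.pos
    chrom = cohort.variants.chrom

    if extractor is not None and ann.tf_of_causal is not None:
        motifs = extractor.motifs
        for ci, k in enumerate(ann.causal_sites):
            motif = motifs[int(ann.tf_of_causal[ci]) % len(motifs)]
            p = int(pos[k])
            start = p - len(motif) // 2
            arr = contigs[str(chrom[k])]
            arr[start : start + len(motif)] = list(motif)
            rb = motif[p - start]
            others = [b for b in "ACGT" if b != rb]
            ref[k] = rb
            alt[k] = others[int(rng.integers(0, 3))]

    # make all remaining ref alleles agree with the contig sequence
    for k in range(cohort.m):
        arr = contigs[str(chrom[k])]
        have = arr[int(pos[k])]
        if ref[k] != have:
            ref[k] = str(have)
            if alt[k] == ref[k]:
                alt[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[str(have)]
    return {name: "".join(arr) for name, arr in contigs.items()}


def simulate_dataset(
    cfg: SimConfig,
    window_cfg: WindowConfig | None = None,
    extractor=None,
) -> SimDataset:
    """Run the full simulation: cohort, annotations, effects, phenotypes.

    Passing ``window_cfg`` builds reference contigs sized for window
    tiling; additionally passing a synthetic ``extractor`` activates
    sequence-coupled mode, in which causal alternate alleles disrupt
    planted TF motifs that the extractor's features detect.
    """
    cohort = simulate_cohort(cfg)
    ann = build_annotations(cohort, sequence_coupled=extractor is not None)
    contigs = None
    if window_cfg is not None:
        contigs = _build_reference(cohort, ann, window_cfg, extractor=extractor)
    X = normalize_genotypes(cohort)
    draws = draw_effects(cohort, ann)
    components = compute_liability(X, ann, draws, cfg)
    components = assign_phenotypes(components, cfg)
    return SimDataset(
        cfg=cfg,
        cohort=cohort,
        annotations=ann,
        draws=draws,
        components=components,
        contigs=contigs,
        window_cfg=window_cfg,
    )


def run_replicates(settings: dict[str, SimConfig], n_reps: int, runner, master_seed: int = 0) -> pd.DataFrame:
    """Repeat each simulation setting with fresh deterministic seeds.

    ``runner(cfg, replicate)`` receives a config whose seed has been
    replaced by a child of the master seed and returns a dict of metric
    columns.  One tidy row per (setting, replicate, runner-row).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for name, base in settings.items():
        for rep in range(n_reps):
            cfg = replace(base, seed=child_seed(master_seed, name, rep))
            out = runner(cfg, rep)
            out_rows = out if isinstance(out, list) else [out]
            for r in out_rows:
                rows.append({"setting": name, "replicate": rep, "seed": cfg.seed, **r})
    return pd.DataFrame(rows)
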