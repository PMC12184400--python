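"""Method benchmarking on simulated cohorts.

Runs the feature-based predictor ("epi-prs": personal sequences ->
synthetic extractor -> per-bin PCA -> GBRT) against genotype baselines
(GBRT on raw dosages, GBRT on PCA-compressed dosages, L2 logistic
regression on standardized dosages) on one simulated dataset, with all
methods sharing the identical stratified split, and aggregates results
over replicated settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from epiprs import genome
from epiprs.extract import FeatureStore, SyntheticExtractor, extract_cohort
from epiprs.model import (
    GBRTConfig,
    SplitSpec,
    auroc,
    dosage_pca_features,
    lambda_index,
    split_cohort,
    train,
)
from epiprs.reduce import ReductionConfig, concat_blocks, fit_block_models, reduce_cohort
from epiprs.simulate import SimConfig, SimDataset, child_seed, run_replicates, simulate_dataset
from epiprs.windows import WindowConfig, tile_block

__all__ = ["BenchmarkConfig", "epi_prs_features", "run_benchmark", "benchmark_grid"]

ALL_METHODS = ("epi-prs", "genotype-gbrt", "genotype-pca-gbrt", "linear-baseline")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Geometry, reduction and model settings shared by one benchmark."""

    window: WindowConfig = WindowConfig(input_length=4096, n_bins=16, bin_size=128)
    reduction: ReductionConfig = ReductionConfig(d_prime=5, combine="mean")
    gbrt: GBRTConfig = GBRTConfig()
    extractor_d: int = 24
    extractor_n_motifs: int = 8
    extractor_flank: int = 32
    extractor_seed: int = 7
    dosage_pca_components: int = 50
    methods: tuple[str, ...] = ALL_METHODS

    def make_extractor(self) -> SyntheticExtractor:
        return SyntheticExtractor(
            self.window,
            d=self.extractor_d,
            n_motifs=self.extractor_n_motifs,
            flank=self.extractor_flank,
            seed=self.extractor_seed,
        )


def cohort_haplotypes(ds: SimDataset) -> dict[str, dict[str, genome.HaplotypePair]]:
    """Whole-contig personal haplotype pairs for every sample.

    Uses the standard genome-construction path (reference substitution
    of phased SNVs), one pair per (sample, contig).
    """
    if ds.contigs is None:
        raise ValueError("dataset has no reference contigs; simulate with a window_cfg")
    pairs: dict[str, dict[str, genome.HaplotypePair]] = {}
    by_chrom = {
        name: ds.cohort.variants.subset_region(name, 0, len(seq))
        for name, seq in ds.contigs.items()
    }
    for sample in ds.samples:
        pairs[sample] = {}
        for name, seq in ds.contigs.items():
            pairs[sample][name] = genome.build_haplotypes(
                seq, by_chrom[name], sample, name, 0, len(seq)
            )
    return pairs


def epi_prs_features(
    ds: SimDataset,
    extractor: SyntheticExtractor,
    reduction: ReductionConfig,
    train_idx: np.ndarray,
    block_ids: list[str] | None = None,
) -> np.ndarray:
    """Reduced block features for every sample (PCA fitted on train only).

    Tiles each (selected) block, builds personal sequences, extracts
    features with caching, fits per-bin PCA on the training split, and
    concatenates the reduced vectors across blocks in canonical order.
    """
    blocks = ds.cohort.blocks
    if block_ids is not None:
        blocks = [b for b in blocks if b.id in set(block_ids)]
        if not blocks:
            raise ValueError("no blocks left after selection")
    pairs = cohort_haplotypes(ds)
    samples = ds.samples
    train_samples = [samples[i] for i in train_idx]

    per_block: dict[str, np.ndarray] = {}
    for blk in blocks:
        windows = tile_block(blk, extractor.window_cfg, contig_length=len(ds.contigs[blk.chrom]))

        def seq_provider(sample: str, w) -> tuple[str, str]:
            hp = pairs[sample][w.chrom]
            return (
                hp.hap1[w.input_start : w.input_end],
                hp.hap2[w.input_start : w.input_end],
            )

        store = extract_cohort(seq_provider, samples, windows, extractor, cache=True)
        models = fit_block_models(store, windows, train_samples, reduction)
        per_block[blk.id] = reduce_cohort(store, windows, samples, models, reduction)
    return concat_blocks(per_block)


def run_benchmark(
    ds: SimDataset,
    cfg: BenchmarkConfig,
    split: SplitSpec,
    block_ids: list[str] | None = None,
    model_seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the configured methods on one dataset with a shared split.

    Returns one row per method: auROC (A), lambda, n_test, and a hash of
    the test-sample index set certifying the shared split.
    """
    labels = np.asarray(ds.labels)
    tr, te = split_cohort(labels, split)
    test_hash = int(np.int64(hash(tuple(te.tolist()))) & 0x7FFFFFFF)
    dos = ds.cohort.dosages().astype(np.float64)

    rows = []
    for method in cfg.methods:
        if method == "epi-prs":
            feats = epi_prs_features(
                ds, cfg.make_extractor(), cfg.reduction, tr, block_ids=block_ids
            )
            f_tr, f_te = feats[tr], feats[te]
            kind = "gbrt-classify"
        elif method == "genotype-gbrt":
            f_tr, f_te = dos[tr], dos[te]
            kind = "gbrt-classify"
        elif method == "genotype-pca-gbrt":
            f_tr, f_te = dosage_pca_features(
                dos[tr], dos[te], n_components=cfg.dosage_pca_components, seed=model_seed
            )
            kind = "gbrt-classify"
        elif method == "linear-baseline":
            mean, sd = dos[tr].mean(axis=0), dos[tr].std(axis=0)
            sd[sd == 0] = 1.0
            f_tr, f_te = (dos[tr] - mean) / sd, (dos[te] - mean) / sd
            kind = "linear-penalized"
        else:
            raise ValueError(f"unknown method {method!r}")

        mdl = train(f_tr, labels[tr], kind=kind, gbrt=cfg.gbrt, seed=model_seed)
        a = auroc(mdl.predict_scores(f_te), labels[te])
        rows.append(
            {
                "method": method,
                "A": a,
                "lambda": lambda_index(a),
                "n_test": int(te.size),
                "test_hash": test_hash,
            }
        )
    return pd.DataFrame(rows)


def benchmark_grid(
    settings: dict[str, SimConfig],
    bench: BenchmarkConfig,
    n_reps: int = 20,
    master_seed: int = 0,
    train_fraction: float = 0.8,
    sequence_coupled: bool = True,
) -> pd.DataFrame:
    """Replicate a grid of simulation settings and benchmark each cohort.

    Per (setting, replicate) a fresh cohort is simulated with a child
    seed, every method is evaluated on the same stratified split, and
    one tidy row per (setting, replicate, method) is returned.
    """
    extractor = bench.make_extractor() if sequence_coupled else None

    def runner(cfg: SimConfig, rep: int):
        ds = simulate_dataset(cfg, window_cfg=bench.window, extractor=extractor)
        split = SplitSpec(train_fraction=train_fraction, seed=child_seed(cfg.seed, "split"))
        res = run_benchmark(ds, bench, split, model_seed=child_seed(cfg.seed, "model"))
        return res.to_dict("records")

    return run_replicates(settings, n_reps, runner, master_seed=master_seed)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean A and lambda per (setting, method) across replicates."""
    return (
        results.groupby(["setting", "method"], as_index=False)
        .agg(mean_A=("A", "mean"), sd_A=("A", "std"), mean_lambda=("lambda", "mean"),
             n_reps=("replicate", "nunique"))
    )
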