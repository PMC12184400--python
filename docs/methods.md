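# Methods

## Overview

`epiprs` implements an epigenome-mediated polygenic risk score: instead
of weighting allele dosages directly, it reconstructs each individual's
two phased haplotype sequences, imputes epigenomic signal tracks from
sequence over a grid of 128 bp bins, compresses those tracks with a
per-bin PCA fitted across the cohort, and trains a gradient-boosted tree
(GBRT) classifier on the concatenated reduced features of LD blocks
enriched for GWAS signal. A regulatory phenotype simulator generates
phased cohorts, annotations and binary traits so the whole chain is
testable end to end. This note records the model, the parameters that
matter, and the design choices made where the design was genuinely open.

## Personal genomes

Only bi-allelic SNVs are used (multi-allelic records are split; indels
are filtered out), so both personal sequences of a region always equal
the region length and differ from the reference only at carried sites.
Phasing is required; statistical phasing cannot assign parent of origin,
so the two haplotypes are arbitrary slots and every downstream consumer
is order-invariant under the default diploid combination rule. Missing
genotypes are imputed to homozygous reference with a counted warning —
a documented choice, since consensus builders differ here. Internal
coordinates are 0-based half-open; VCF positions are converted at the
I/O boundary.

## Window geometry

The extractor contract mirrors large sequence models: a fixed input
(196,608 bp by default) scored over 896 central non-overlapping 128 bp
bins (114,688 bp; note that 896 × 128 = 114,688). Blocks are tiled with
stride equal to the central length so central bins partition an interval
covering the block; input flanks overlap. The stride is a design choice
— it is the simplest tiling producing full coverage without duplicated
features. Blocks shorter than one central region get a single window
centred on the block midpoint. Windows that would run off the contig are
shifted inward and flagged. All geometry is configurable; tests and the
simulator use a 4,096 bp input with 16 bins, exercising identical code
paths at desk scale.

## Synthetic feature extractor

Real sequence-to-epigenome models are GPU-scale and weight-dependent, so
the package defines only the extraction contract (sequence in, bins ×
tracks out) and ships a deterministic synthetic extractor: per bin it
counts occurrences of `n_motifs` seeded consensus motifs within the bin
± a flank (32 bp default), appends the GC fraction of the same window,
and maps this summary through a fixed seeded linear projection and a
softplus to `d` tracks. Consequences that the tests rely on:

* locality — a base substitution can only affect bins within
  `flank + max_motif_length − 1` bp (the declared receptive flank);
* traceability — planting or destroying one motif instance changes one
  count by exactly one, giving a ground-truth chain from variant to
  feature.

What it does not emulate: long-range regulatory interactions, cell-type
specific chromatin context, or the graded binding affinities of real
TFs. Passing tests therefore demonstrate the pipeline's mechanics and
its statistical behaviour under a known generative chain, not predictive
performance on real genomes.

## Per-bin PCA

For each (window, bin), the feature vectors of both haplotypes of every
training individual are pooled as observations and a PCA retains
`d′ = 5` components (covariance eigenvectors via SVD; component signs
fixed by forcing the largest-magnitude loading positive for backend
reproducibility). Centering uses the pooled haplotype mean; tracks are
not rescaled (they are model outputs on comparable scales). The fit
population is the training split only — test individuals are projected
with frozen models, never entering the fit. A sample's two haplotype
projections are averaged by default (order-invariant and consistent with
counting one d′-vector per bin per individual: 896 bins × 5 components =
4,480 features per window); `sum` and `concat` rules are available.
Rank-deficient bins keep their rank components and pad projections with
zeros.

## Phenotype simulator

Liability is the sum of four components plus an intercept:

    g(mu_i) = alpha0 + y_epi + y_direct + y_env + y_inter

* epigenetic: `y_epi_i = sum_g sum_t sum_{k in S_g} X_ik B_tk e_gtk`
  with `e_gtk ~ N(0, sigma_t^2)` and `sigma_t^2 ~ InvGamma(shape 3,
  scale 1)` (shape/scale reading; mean 1/2);
* direct: sum of `X_ik beta_k`, `beta_k ~ N(0,1)`, over SNPs outside
  all causal-gene regulatory elements;
* interaction: products of disjoint random pairs of causal genotypes
  with N(0,1) coefficients, `round(f_inter * n_causal / 2)` pairs;
* environment: independent Gaussian.

`X` is the per-site standardized dosage matrix (the conventional
"normalized genotype"). Each genetic component is affinely rescaled to
population variance exactly `h_epi²`, `h_direct²`, `h_inter²`; the
environmental variance is the remainder, so liability variance is ~1.
Labels come from thresholding (case count exactly `round(n·prevalence)`,
ties broken by a seeded order; default, prevalence 0.5) or a Bernoulli
draw whose logit intercept is solved by bracketed root finding to hit
the prevalence within 1e-8.

Genotypes are Bernoulli(MAF) per haplotype (optional AR(1) latent
Gaussian for within-block LD, off by default), with a configurable rare
fraction of causal variants drawn from MAF ∈ [0.001, 0.01) ("rare" =
MAF < 0.01, the conventional cutoff) and everything else from
[0.05, 0.5]. Defaults follow the study design the simulator emulates:
one causal gene per block, 100 causal variants per gene, 20 replicates
per setting. Regulatory elements are placed constructively around the
causal variants (all within 1 Mb of the gene anchor), so causal sites
overlap REs exactly and the direct-effect SNP set is exactly the non-RE
sites; the TF set size is a parameter (the expression filter that
selects TFs in real data only determines this count).

In *sequence-coupled* mode each causal variant is assigned one binding
TF, that TF's consensus motif is planted in the reference centred on the
site, and the alternate allele breaks the motif match — so causal
alleles genuinely move the extractor's features, closing the loop
genotype → sequence → feature → phenotype. One TF per causal site is a
deliberate simplification: a planted motif instance can encode only one
binding. Non-coupled mode draws the binding matrix Bernoulli per TF.

A consequence of weighting *normalized* genotypes: every causal site
explains the same liability variance regardless of MAF, so single-site
association χ² is approximately MAF-independent. The rare-variant dial
manifests instead as carrier sparsity — a rare site's signal sits in a
handful of individuals, degrading per-variant effect *estimation* and
hence out-of-sample linear prediction, which is the collapse the
benchmark measures.

## Block selection and risk models

A block is selected iff it contains one variant with p < P0 (half-open
containment of the 0-based position). Built-in summary statistics come
from a per-site allelic chi-square (1 df, no continuity correction) run
on the training split only; external GWAS summary statistics bypass the
scan. LD-aware clumping is out of scope.

The GBRT uses 500 trees, depth 3, learning rate 0.05, subsample 0.8,
with early stopping on a 10% carve-out (hyperparameters exposed).
Baselines: GBRT on raw dosages, GBRT on PCA-compressed standardized
dosages (50 components), and an L2-penalized logistic regression on
standardized dosages — a deliberate stand-in for summary-statistic
linear PRS methods, preserving the linear-vs-nonlinear contrast without
external LD-reference machinery. Default multi-block strategy is
feature concatenation in canonical block order; an optimally weighted
per-block score combination (logistic regression on per-block training
scores) is available. auROC is computed from rank sums with ties
counting one half; the relative-gain index is λ = (A − 0.5)/0.5.

## Importance analyses

Track importance fits one small GBRT (100 trees) per bin on that bin's
raw tracks and averages normalized Gini vectors across bins (bins with
constant features are skipped and the divisor adjusted; whether to
average raw or normalized scores was open — normalized keeps bins
comparable). Bin importance group-averages the main model's per-PC Gini
importances through the (bin, component) mapping. Top/bottom quantile
sets (floor(q·M), minimum 1, ties broken by bin order) can be
intersected with annotation BED tracks; a bin overlaps iff its genomic
interval intersects any (or every) track interval, with an optional
conditional fraction against a second track.

## Reduced-scale benchmark designs

The replicated simulation studies run at desk scale with the shrunken
window geometry and the synthetic extractor, 20 replicates per setting,
stratified 80/20 splits shared by all methods within a replicate:

* interaction axis: n = 4,000, m = 100, 40 causal, h_inter² = 0.7
  (f_inter = 0.4), h_direct² = 0.2 — the nonlinear-vs-linear gap needs a
  large training set, so this axis uses the largest cohorts;
* rare-fraction axis: n = 1,000, m = 100, 50 causal, h_epi² = 0.9,
  h_direct² = 0.05, rare fraction ∈ {0, 0.5, 1};
* epigenetic-proportion axis: n = 1,000, m = 100, 50 causal,
  h_epi² ∈ {0, 0.45, 0.9} with h_direct² = 0.9 − h_epi², so total
  genetic variance is constant and only the channel shifts;
* null control: n = 1,000, all variance components zero.

m = 100 with 50 causal keeps the direct- and regulatory-channel
architectures comparable in site count, so the epigenetic axis varies
the channel rather than the concentration of signal.

## Numerical choices and degenerate inputs

Seeds: every stochastic stage consumes a named child seed derived from
the master seed by SHA-256 (stable across processes and below 2³¹).
Monomorphic sites are redrawn up to 100 times, then an error suggests a
larger n. A genetic component that is constant while its target variance
is positive raises rather than silently rescaling. Zero-variance score
columns are dropped (with a warning) before score combination. PCA sign
fixing and stable tie-breaks (bin order, seeded permutations) make all
tabular outputs bit-stable across reruns.

## Known limitations

No indels or structural variants; no population structure, relatedness
or geographic confounding in the simulator; no external-summary-statistic
PRS implementations; the synthetic extractor's feature map is linear in
motif counts and cannot represent saturating or cooperative regulatory
logic; prediction quality on real data is explicitly out of reach of the
bundled extractor.
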