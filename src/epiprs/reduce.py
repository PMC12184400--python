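"""Per-bin local PCA and block-level feature assembly.

The extractor emits d tracks per bin; across a cohort each bin therefore
defines a cloud of 2N vectors (both haplotypes of every training
individual enter as separate observations).  A PCA fitted per bin on the
training split compresses each bin to d' components (default 5); a
sample's two haplotype projections are combined — by default averaged,
which makes the result invariant to the arbitrary phasing order — and
the per-bin vectors are concatenated in (window, bin) order into one
block-level feature vector of length M x d', where M is the total bin
count across the block's windows.  With the full geometry (M = 896 bins
per window, d' = 5) one window contributes 4,480 predictor features.

PCA models are fitted on the training split only and frozen before any
test individual is transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from epiprs.extract import FeatureStore
from epiprs.windows import GenomicWindow

__all__ = [
    "ReductionConfig",
    "BinPCAModel",
    "fit_bin_pca",
    "fit_block_models",
    "reduce_sample",
    "reduce_cohort",
    "concat_blocks",
]


@dataclass(frozen=True)
class ReductionConfig:
    """How to reduce per-bin features to a per-individual vector.

    d_prime : components kept per bin (default 5).
    combine : diploid combination of the two haplotype projections —
        "mean" (default, order-invariant), "sum" (order-invariant), or
        "concat" (keeps both, order-dependent).
    """

    d_prime: int = 5
    combine: str = "mean"

    def __post_init__(self) -> None:
        if self.d_prime < 1:
            raise ValueError("d_prime must be >= 1")
        if self.combine not in ("mean", "sum", "concat"):
            raise ValueError(f"unknown combine rule {self.combine!r}")

    @property
    def values_per_bin(self) -> int:
        return self.d_prime * (2 if self.combine == "concat" else 1)


@dataclass
class BinPCAModel:
    """Frozen PCA for one (window, bin): mean, components, variance."""

    window_id: str
    bin_index: int
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (d_eff, d), orthonormal rows
    explained_variance_ratio: np.ndarray  # (d_eff,), non-increasing
    d_prime: int  # requested component count
    rank_deficient: bool = False

    @property
    def d_eff(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project centered vectors; pads with zeros if rank < d_prime."""
        proj = (np.atleast_2d(x) - self.mean) @ self.components.T
        if self.d_eff < self.d_prime:
            pad = np.zeros((proj.shape[0], self.d_prime - self.d_eff))
            proj = np.hstack([proj, pad])
        return proj if x.ndim == 2 else proj[0]


def fit_bin_pca(vectors: np.ndarray, d_prime: int, window_id: str = "", bin_index: int = 0) -> BinPCAModel:
    """Fit PCA on the pooled haplotype feature vectors of one bin.

    ``vectors`` is (n_obs, d) with both haplotypes of every training
    individual stacked as rows.  Components are the top-``d_prime``
    eigenvectors of the sample covariance, computed by SVD of the
    centered matrix; each component's sign is fixed by forcing its
    largest-magnitude loading positive, so results are reproducible
    across linear-algebra backends.  If the data rank is below
    ``d_prime`` the model keeps only the rank components and is flagged.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit a bin PCA")
    n, d = vectors.shape
    mean = vectors.mean(axis=0)
    centered = vectors - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)

    var = s**2 / (n - 1)
    total = var.sum()
    tol = s[0] * max(n, d) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int((s > tol).sum())
    d_eff = min(d_prime, rank)
    rank_deficient = d_eff < d_prime

    components = vt[:d_eff].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    ratio = var[:d_eff] / total if total > 0 else np.zeros(d_eff)
    return BinPCAModel(
        window_id=window_id,
        bin_index=bin_index,
        mean=mean,
        components=components,
        explained_variance_ratio=ratio,
        d_prime=d_prime,
        rank_deficient=rank_deficient,
    )


def fit_block_models(
    store: FeatureStore,
    windows: list[GenomicWindow],
    train_samples: list[str],
    cfg: ReductionConfig,
) -> dict[tuple[str, int], BinPCAModel]:
    """Fit one BinPCAModel per (window, bin) on the training split.

    Only ``train_samples``' tensors are read, so no information from
    held-out individuals leaks into the projection.
    """
    models: dict[tuple[str, int], BinPCAModel] = {}
    for w in windows:
        # (2*n_train, k, d): both haplotypes pooled as observations
        stacked = np.stack(
            [store.get(s, h, w.id) for s in train_samples for h in (1, 2)]
        )
        for i in range(w.cfg.n_bins):
            models[(w.id, i)] = fit_bin_pca(
                stacked[:, i, :], cfg.d_prime, window_id=w.id, bin_index=i
            )
    return models


def reduce_sample(
    store: FeatureStore,
    windows: list[GenomicWindow],
    sample: str,
    models: dict[tuple[str, int], BinPCAModel],
    cfg: ReductionConfig,
) -> np.ndarray:
    """One individual's concatenated reduced feature vector for a block.

    Per bin, both haplotype rows are centered and projected with the
    frozen bin model, combined per the diploid rule, and concatenated in
    (window, bin) order.  Length is M x d' for mean/sum, 2 x M x d' for
    concat.
    """
    pieces: list[np.ndarray] = []
    for w in windows:
        t1 = store.get(sample, 1, w.id)
        t2 = store.get(sample, 2, w.id)
        for i in range(w.cfg.n_bins):
            try:
                model = models[(w.id, i)]
            except KeyError:
                raise KeyError(f"no PCA model for window {w.id!r} bin {i}") from None
            r1 = model.transform(t1[i])
            r2 = model.transform(t2[i])
            if cfg.combine == "mean":
                pieces.append((r1 + r2) / 2.0)
            elif cfg.combine == "sum":
                pieces.append(r1 + r2)
            else:
                pieces.append(np.concatenate([r1, r2]))
    return np.concatenate(pieces)


def reduce_cohort(
    store: FeatureStore,
    windows: list[GenomicWindow],
    samples: list[str],
    models: dict[tuple[str, int], BinPCAModel],
    cfg: ReductionConfig,
) -> np.ndarray:
    """Reduced vectors for many samples, stacked as an (n, M*d') matrix.

    Equivalent to :func:`reduce_sample` per row but batched per bin
    (one projection matmul over the whole cohort per haplotype).
    """
    pieces: list[np.ndarray] = []
    for w in windows:
        t1 = np.stack([store.get(s, 1, w.id) for s in samples])  # (n, k, d)
        t2 = np.stack([store.get(s, 2, w.id) for s in samples])
        for i in range(w.cfg.n_bins):
            try:
                model = models[(w.id, i)]
            except KeyError:
                raise KeyError(f"no PCA model for window {w.id!r} bin {i}") from None
            r1 = model.transform(t1[:, i, :])
            r2 = model.transform(t2[:, i, :])
            if cfg.combine == "mean":
                pieces.append((r1 + r2) / 2.0)
            elif cfg.combine == "sum":
                pieces.append(r1 + r2)
            else:
                pieces.append(np.hstack([r1, r2]))
    return np.concatenate(pieces, axis=1)


def concat_blocks(block_features: dict[str, np.ndarray]) -> np.ndarray:
    """Concatenate per-block feature matrices in canonical block order.

    ``block_features`` maps block id -> (n, F_b) matrix with rows aligned
    across blocks.  Blocks are concatenated by ascending id, so the
    result is independent of the dict's insertion order.
    """
    if not block_features:
        raise ValueError("no blocks to concatenate")
    order = sorted(block_features)
    n_rows = {block_features[b].shape[0] for b in order}
    if len(n_rows) != 1:
        raise ValueError("blocks disagree on sample count; a sample is missing")
    return np.concatenate([block_features[b] for b in order], axis=1)
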