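"""Feature- and bin-level importance with annotation-overlap enrichment.

Two complementary views of a fitted block model:

* track importance — which of the d raw epigenomic tracks drive
  prediction.  Because the main model sees PCA features, a separate
  small GBRT is fitted per bin directly on that bin's raw d tracks; the
  per-model normalized Gini importance vectors are averaged across bins.
* bin importance — which genomic bins matter.  Each feature of the main
  model maps to exactly one (bin, component); a bin's score is the mean
  Gini importance of its d' components.

Top/bottom importance quantiles of bins can then be intersected with
annotation interval tracks (open chromatin, enhancer marks, ...) to ask
whether important bins are enriched in regulatory sequence.
"""

from __future__ import annotations

import warnings

import numpy as np
from intervaltree import IntervalTree

from epiprs.model import GBRTConfig, RiskModel, train
from epiprs.windows import GenomicWindow

__all__ = [
    "track_importance",
    "bin_importance",
    "quantile_bins",
    "annotation_overlap",
    "bin_genomic_intervals",
]


def track_importance(
    bin_features: list[np.ndarray],
    labels: np.ndarray,
    gbrt: GBRTConfig = GBRTConfig(n_estimators=100),
    seed: int = 0,
) -> np.ndarray:
    """Average per-bin GBRT Gini importances over raw feature tracks.

    ``bin_features`` is one (n, d) matrix per bin.  Each bin gets its own
    classifier; its importance vector is normalized to sum 1 and the
    output is the unweighted mean across bins.  Bins whose features are
    constant everywhere are skipped with a warning and the divisor
    adjusted.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to fit importance models")
    total = None
    used = 0
    for bi, feats in enumerate(bin_features):
        feats = np.asarray(feats, dtype=np.float64)
        if feats.std(axis=0).max() == 0:
            warnings.warn(f"bin {bi}: all features constant; skipped", stacklevel=2)
            continue
        mdl = train(feats, labels, kind="gbrt-classify", gbrt=gbrt, seed=seed)
        imp = mdl.feature_importances()
        s = imp.sum()
        if s > 0:
            imp = imp / s
        total = imp if total is None else total + imp
        used += 1
    if used == 0:
        raise ValueError("no bin had usable features")
    return total / used


def bin_importance(model: RiskModel, n_bins: int, d_prime: int) -> np.ndarray:
    """Bin-level scores from the main model's per-feature importances.

    Feature j of the concatenated block vector belongs to bin j // d',
    component j % d'; a bin's score is the mean importance of its d'
    components.  The model's feature count must equal n_bins * d'.
    """
    imp = model.feature_importances()
    if imp.size != n_bins * d_prime:
        raise ValueError(
            f"model has {imp.size} features; expected {n_bins} bins x {d_prime} "
            f"components = {n_bins * d_prime}"
        )
    return imp.reshape(n_bins, d_prime).mean(axis=1)


def quantile_bins(bin_scores: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top and bottom q-quantile bins.

    Each set has max(1, floor(q * M)) members; ties are broken by bin
    order (stable sort), so the result is deterministic.
    """
    if not 0 < q < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    scores = np.asarray(bin_scores, dtype=np.float64)
    m = scores.size
    k = max(1, int(np.floor(q * m)))
    order = np.argsort(scores, kind="stable")
    return np.sort(order[::-1][:k]), np.sort(order[:k])


def bin_genomic_intervals(windows: list[GenomicWindow]) -> list[tuple[str, int, int]]:
    """Genomic interval of every bin across a block's windows, in
    (window, bin) order — the order block feature vectors use."""
    out = []
    for w in windows:
        for i in range(w.cfg.n_bins):
            s, e = w.bin_interval(i)
            out.append((w.chrom, s, e))
    return out


def annotation_overlap(
    bin_set: np.ndarray,
    bin_intervals: list[tuple[str, int, int]],
    tracks: dict[str, list[tuple[str, int, int]]],
    rule: str = "any",
    conditional_track: str | None = None,
) -> dict:
    """Fraction of a bin set overlapping annotation interval tracks.

    A bin overlaps a track iff its half-open genomic interval intersects
    at least one of the track's intervals; under rule "any" a bin counts
    if it overlaps any track, under "all" only if it overlaps every
    track.  With ``conditional_track`` the report adds the fraction of
    the already-overlapping bins that also intersect that second track
    (e.g. H3K27ac within DNase).
    """
    if len(bin_set) == 0:
        raise ValueError("empty bin set")
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")

    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, ivs in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, s, e in ivs:
            per_chrom.setdefault(chrom, IntervalTree()).addi(s, e)
        trees[name] = per_chrom

    def hits(track: str, chrom: str, s: int, e: int) -> bool:
        tree = trees[track].get(chrom)
        return bool(tree.overlap(s, e)) if tree is not None else False

    main_tracks = [t for t in tracks if t != conditional_track]
    if not main_tracks:
        raise ValueError("no primary tracks after excluding the conditional one")
    overlapping = []
    for b in bin_set:
        chrom, s, e = bin_intervals[int(b)]
        flags = [hits(t, chrom, s, e) for t in main_tracks]
        if (any(flags) if rule == "any" else all(flags)):
            overlapping.append(int(b))

    report = {
        "n_bins": int(len(bin_set)),
        "n_overlapping": len(overlapping),
        "fraction": len(overlapping) / len(bin_set),
    }
    if conditional_track is not None:
        if conditional_track not in tracks:
            raise KeyError(f"unknown conditional track {conditional_track!r}")
        cond = [
            b
            for b in overlapping
            if hits(conditional_track, *bin_intervals[b])
        ]
        report["conditional_n"] = len(cond)
        report["conditional_fraction"] = (
            len(cond) / len(overlapping) if overlapping else float("nan")
        )
    return report
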