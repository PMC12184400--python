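"""GWAS-signal-based LD block selection.

A block enters the risk model iff it contains at least one variant whose
association p-value falls below a predefined threshold P0.  Summary
statistics are either supplied externally (the usual path with biobank
GWAS results) or produced by the built-in per-site allelic chi-square
scan, which is sufficient for ranking blocks on synthetic cohorts.  When
the scan runs inside the prediction pipeline it sees the training split
only, so selection never uses held-out individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from epiprs.windows import LDBlock

__all__ = ["SelectionConfig", "assoc_scan", "select_blocks", "read_summary_stats"]


@dataclass(frozen=True)
class SelectionConfig:
    """P0: the p-value threshold a block must beat to be selected."""

    p0: float = 5e-8

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("P0 must lie in (0, 1)")


def assoc_scan(
    dosages: np.ndarray,
    labels: np.ndarray,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Allelic chi-square association test per site.

    For each site the 2x2 table of allele counts (ref/alt) by case
    status is tested with Pearson's chi-square (1 df, no continuity
    correction); the two-sided p-value is the chi-square survival
    function.  Returns a summary-statistic frame with columns
    id, chrom, pos (1-based), chi2, p.
    """
    dosages = np.asarray(dosages)
    labels = np.asarray(labels).astype(bool)
    n, m = dosages.shape
    if labels.size != n:
        raise ValueError("labels length != number of individuals")
    n_case, n_ctrl = int(labels.sum()), int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both cases and controls are required")

    alt_case = dosages[labels].sum(axis=0).astype(np.float64)
    alt_ctrl = dosages[~labels].sum(axis=0).astype(np.float64)
    ref_case = 2.0 * n_case - alt_case
    ref_ctrl = 2.0 * n_ctrl - alt_ctrl

    alt_tot = alt_case + alt_ctrl
    if np.any(alt_tot == 0) or np.any(alt_tot == 2 * n):
        k = int(np.nonzero((alt_tot == 0) | (alt_tot == 2 * n))[0][0])
        raise ValueError(f"site {k} is monomorphic; filter before scanning")

    total = 2.0 * n
    chi2 = np.zeros(m)
    for obs_a, obs_r, grp in ((alt_case, ref_case, 2.0 * n_case), (alt_ctrl, ref_ctrl, 2.0 * n_ctrl)):
        exp_a = grp * alt_tot / total
        exp_r = grp - exp_a
        chi2 += (obs_a - exp_a) ** 2 / exp_a + (obs_r - exp_r) ** 2 / exp_r
    p = stats.chi2.sf(chi2, df=1)
    # survival function can round to 0 at extreme chi2; p must stay in (0, 1]
    p = np.clip(p, np.finfo(np.float64).tiny, 1.0)

    return pd.DataFrame(
        {
            "id": ids if ids is not None else [f"site{k}" for k in range(m)],
            "chrom": chrom if chrom is not None else np.repeat("chr0", m),
            "pos": (pos + 1) if pos is not None else np.arange(1, m + 1),
            "chi2": chi2,
            "p": p,
        }
    )


def select_blocks(
    stats_table: pd.DataFrame, blocks: list[LDBlock], cfg: SelectionConfig
) -> pd.DataFrame:
    """Select LD blocks containing at least one variant with p < P0.

    Positions in the summary table are 1-based (as printed in GWAS
    output) and block intervals 0-based half-open; a variant at printed
    position q lies in block [s, e) iff s <= q-1 < e.  Returns one row
    per block: id, interval, number of significant variants, minimum p,
    selected flag.  Variants falling outside all blocks are counted in
    the frame's ``attrs["n_outside"]``.
    """
    pos0 = stats_table["pos"].to_numpy() - 1
    chroms = stats_table["chrom"].astype(str).to_numpy()
    p = stats_table["p"].to_numpy()
    sig = p < cfg.p0

    assigned = np.zeros(len(stats_table), dtype=bool)
    rows = []
    for blk in blocks:
        inside = (chroms == blk.chrom) & (pos0 >= blk.start) & (pos0 < blk.end)
        assigned |= inside
        n_sig = int((inside & sig).sum())
        rows.append(
            {
                "block": blk.id,
                "chrom": blk.chrom,
                "start": blk.start,
                "end": blk.end,
                "n_sig": n_sig,
                "min_p": float(p[inside].min()) if inside.any() else np.nan,
                "selected": n_sig > 0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_outside"] = int((~assigned).sum())
    return out


def read_summary_stats(path: str) -> pd.DataFrame:
    """Read external GWAS summary statistics (TSV: chrom, pos, id, p)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "id", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return df
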