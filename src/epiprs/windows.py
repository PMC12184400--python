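"""Window geometry: tiling LD blocks into fixed-size model input windows.

A sequence-to-feature extractor consumes a fixed-length input (196,608 bp
for the default geometry) and emits features for a central grid of
``n_bins`` non-overlapping bins of ``bin_size`` bp (896 x 128 bp =
114,688 bp central region by default), leaving an equal flank on either
side.  LD blocks are usually longer than one central region, so each
block is tiled left-to-right with stride equal to the central length:
input windows overlap in their flanks but the central bins partition an
interval covering the whole block without gaps or duplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "WindowConfig",
    "GenomicWindow",
    "LDBlock",
    "tile_block",
    "bin_coordinates",
    "locate_bin",
    "read_blocks_bed",
    "windows_to_bed",
]


@dataclass(frozen=True)
class WindowConfig:
    """Geometry of one extractor input window.

    Defaults match the Enformer-style geometry: a 196,608 bp input whose
    central 896 x 128 bp = 114,688 bp carry the output bins.  Smaller
    geometries (e.g. 4,096 bp input with 16 bins) exercise the identical
    code paths at desk scale.
    """

    input_length: int = 196_608
    n_bins: int = 896
    bin_size: int = 128

    def __post_init__(self) -> None:
        if self.central_length > self.input_length:
            raise ValueError(
                f"central region {self.central_length} bp exceeds input "
                f"length {self.input_length} bp"
            )
        if (self.input_length - self.central_length) % 2 != 0:
            raise ValueError("flank (input_length - n_bins*bin_size) must be even")

    @property
    def central_length(self) -> int:
        return self.n_bins * self.bin_size

    @property
    def flank(self) -> int:
        """Length of the unscored margin on each side of the central region."""
        return (self.input_length - self.central_length) // 2


@dataclass(frozen=True)
class LDBlock:
    """One linkage-disequilibrium block: a 0-based half-open interval."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"block {self.id}: empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicWindow:
    """One extractor input window with its central bin grid.

    All coordinates are 0-based half-open.  ``shifted`` records that the
    window had to be moved inward to stay on the contig.
    """

    chrom: str
    input_start: int
    cfg: WindowConfig
    id: str = ""
    shifted: bool = False

    @property
    def input_end(self) -> int:
        return self.input_start + self.cfg.input_length

    @property
    def central_start(self) -> int:
        return self.input_start + self.cfg.flank

    @property
    def central_end(self) -> int:
        return self.central_start + self.cfg.central_length

    def bin_interval(self, i: int) -> tuple[int, int]:
        if not 0 <= i < self.cfg.n_bins:
            raise IndexError(f"bin index {i} outside [0, {self.cfg.n_bins})")
        s = self.central_start + i * self.cfg.bin_size
        return s, s + self.cfg.bin_size


def tile_block(
    block: LDBlock,
    cfg: WindowConfig,
    contig_length: int | None = None,
) -> list[GenomicWindow]:
    """Tile an LD block with extractor windows.

    Central regions are laid left-to-right from the block start with
    stride equal to the central length, so their bins partition an
    interval covering the whole block; the last window's central region
    may extend past the block end.  A block shorter than one central
    region gets a single window centred on the block midpoint.  Windows
    whose input interval would leave the contig are shifted inward and
    flagged.

    Parameters
    ----------
    block : LDBlock
    cfg : WindowConfig
    contig_length : int, optional
        If given, windows are kept inside ``[0, contig_length)``; a
        contig shorter than one input window is an error.
    """
    if contig_length is not None and contig_length < cfg.input_length:
        raise ValueError(
            f"contig for block {block.id} is {contig_length} bp, shorter than "
            f"the {cfg.input_length} bp input window"
        )
    central, flank = cfg.central_length, cfg.flank
    n_windows = -(-block.length // central)  # ceil
    if block.length < central:
        # degenerate short block: one window centred on the block midpoint
        mid = (block.start + block.end) // 2
        starts = [mid - central // 2 - flank]
    else:
        starts = [block.start - flank + j * central for j in range(n_windows)]

    windows: list[GenomicWindow] = []
    for j, s in enumerate(starts):
        shifted = False
        if s < 0:
            s, shifted = 0, True
        if contig_length is not None and s + cfg.input_length > contig_length:
            s, shifted = contig_length - cfg.input_length, True
        windows.append(
            GenomicWindow(
                chrom=block.chrom,
                input_start=s,
                cfg=cfg,
                id=f"{block.id}.w{j}",
                shifted=shifted,
            )
        )
    return windows


def bin_coordinates(window: GenomicWindow) -> list[tuple[int, int]]:
    """Return the ordered half-open intervals of the window's central bins."""
    return [window.bin_interval(i) for i in range(window.cfg.n_bins)]


def locate_bin(window: GenomicWindow, position: int) -> int | None:
    """Map a 0-based genomic position to its bin index, or None if the
    position falls outside the window's central region."""
    if not window.central_start <= position < window.central_end:
        return None
    return (position - window.central_start) // window.cfg.bin_size


def read_blocks_bed(path: str) -> list[LDBlock]:
    """Read LD block definitions from a BED file (0-based half-open).

    The optional 4th column supplies block ids; otherwise ids are
    ``<chrom>:<start>-<end>``.  Blocks are returned sorted by
    (chrom, start) and checked for within-chromosome overlap.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            bid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append(LDBlock(id=bid, chrom=chrom, start=start, end=end))
    rows.sort(key=lambda b: (b.chrom, b.start))
    for a, b in zip(rows, rows[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping LD blocks {a.id} and {b.id}")
    return rows


def windows_to_bed(windows: list[GenomicWindow]) -> pd.DataFrame:
    """Window manifest as a BED-like frame (central intervals)."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.central_start for w in windows],
            "end": [w.central_end for w in windows],
            "name": [w.id for w in windows],
            "input_start": [w.input_start for w in windows],
            "input_end": [w.input_end for w in windows],
            "shifted": [w.shifted for w in windows],
        }
    )
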