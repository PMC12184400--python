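"""Personal diploid genome construction from phased SNVs.

Given a reference sequence and phased genotypes, each individual's two
haplotype sequences over a region are obtained by substituting the
alternate base at every site carried on that haplotype.  Only
single-nucleotide variants are supported: insertions and deletions are
filtered out up front, so both personal sequences always have exactly
the region's length and differ from the reference only at variant
positions.

Statistical phasing cannot assign parent of origin, so the two
haplotypes are arbitrary slots ("hap1" = first phased allele, "hap2" =
second); every downstream consumer is order-invariant in the pair.
Coordinates are 0-based half-open internally; VCF's 1-based positions
are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RawVariant",
    "PhasedVariants",
    "HaplotypePair",
    "filter_snvs",
    "build_haplotypes",
    "read_phased_vcf",
    "write_haplotype_fasta",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RawVariant:
    """One parsed variant record, possibly multi-allelic, before filtering.

    ``genotypes`` holds per-sample allele index pairs (n_samples, 2);
    -1 marks a missing allele.  ``phased`` flags whether each sample's
    genotype carried the ``|`` separator.
    """

    chrom: str
    pos1: int  # 1-based, as printed in VCF
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    phased: np.ndarray


@dataclass
class PhasedVariants:
    """Bi-allelic phased SNVs for a cohort.

    Attributes
    ----------
    samples : list of sample ids.
    chrom, pos : arrays of contig names and 0-based positions.
    ref, alt : arrays of single reference / alternate bases.
    haplotypes : int8 array (n_sites, n_samples, 2) of allele indicators
        in {0, 1}; axis 2 is the phased allele order.
    n_missing_filled : count of missing alleles imputed to reference.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    n_missing_filled: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_samples, n_sites) in {0, 1, 2}."""
        return self.haplotypes.sum(axis=2).T.astype(np.int8)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_region(self, chrom: str, start: int, end: int) -> "PhasedVariants":
        """Restrict to sites with 0-based position in [start, end)."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)
        return PhasedVariants(
            samples=self.samples,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            haplotypes=self.haplotypes[mask],
            n_missing_filled=self.n_missing_filled,
        )


@dataclass(frozen=True)
class HaplotypePair:
    """The two personal sequences of one sample over one region."""

    sample: str
    chrom: str
    start: int  # 0-based half-open region
    end: int
    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        length = self.end - self.start
        if len(self.hap1) != length or len(self.hap2) != length:
            raise ValueError(
                f"haplotype length mismatch for {self.sample}: region is "
                f"{length} bp, sequences are {len(self.hap1)}/{len(self.hap2)} bp"
            )


def filter_snvs(records: list[RawVariant], samples: list[str]) -> PhasedVariants:
    """Retain bi-allelic SNVs from parsed variant records.

    Indels (any allele longer than one base, or symbolic/breakend
    alleles) are dropped.  Multi-allelic SNV records are split into one
    bi-allelic record per alternate base, each carrying the indicator of
    its own alt allele, so per-sample indicators across the split records
    sum to the original non-reference allele count.

    Missing alleles are imputed to reference with a counted warning.
    An unphased heterozygous genotype in a retained record is an error:
    phasing is a precondition of haplotype construction.
    """
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    haps: list[np.ndarray] = []
    n_missing = 0

    for rec in records:
        if len(rec.ref) != 1 or rec.ref not in _VALID_BASES:
            continue
        snv_alts = [
            (ai + 1, a)
            for ai, a in enumerate(rec.alts)
            if len(a) == 1 and a in _VALID_BASES and a != rec.ref
        ]
        if not snv_alts:
            continue

        gt = rec.genotypes
        missing = gt < 0
        if missing.any():
            n_missing += int(missing.sum())
            gt = np.where(missing, 0, gt)
        het = gt[:, 0] != gt[:, 1]
        bad = het & ~rec.phased
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"unphased heterozygous genotype for sample {samples[i]!r} at "
                f"{rec.chrom}:{rec.pos1}; phased genotypes are required"
            )
        for allele_idx, alt in snv_alts:
            chroms.append(rec.chrom)
            positions.append(rec.pos1 - 1)
            refs.append(rec.ref)
            alts.append(alt)
            haps.append((gt == allele_idx).astype(np.int8))

    if n_missing:
        warnings.warn(
            f"{n_missing} missing alleles treated as homozygous reference",
            stacklevel=2,
        )

    n = len(samples)
    out = PhasedVariants(
        samples=list(samples),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        haplotypes=(
            np.stack(haps) if haps else np.zeros((0, n, 2), dtype=np.int8)
        ),
        n_missing_filled=n_missing,
    )
    order = np.lexsort((out.alt.astype(str), out.pos, out.chrom.astype(str)))
    out.chrom = out.chrom[order]
    out.pos = out.pos[order]
    out.ref = out.ref[order]
    out.alt = out.alt[order]
    out.haplotypes = out.haplotypes[order]

    key = list(zip(out.chrom, out.pos, out.alt))
    if len(set(key)) != len(key):
        dup = next(k for k in key if key.count(k) > 1)
        raise ValueError(f"duplicate variant record at {dup[0]}:{dup[1] + 1} alt={dup[2]}")
    return out


def build_haplotypes(
    reference: str,
    variants: PhasedVariants,
    sample: str,
    chrom: str,
    start: int,
    end: int,
) -> HaplotypePair:
    """Substitute a sample's phased alleles into the reference sequence.

    ``reference`` must be the uppercase sequence of ``[start, end)`` on
    ``chrom``.  Each retained SNV whose indicator is 1 on a haplotype
    replaces the reference base at its position in that haplotype only.

    Raises
    ------
    ValueError
        If a variant's stated reference base disagrees with the supplied
        reference sequence (including variants at N positions), or a
        variant position falls outside the region.
    """
    region_len = end - start
    if len(reference) != region_len:
        raise ValueError(
            f"reference is {len(reference)} bp but region {chrom}:{start}-{end} "
            f"is {region_len} bp"
        )
    local = variants.subset_region(chrom, start, end)
    if ((variants.chrom == chrom).sum() != local.n_sites):
        off = variants.subset_region(chrom, 0, start).n_sites
        if off or variants.subset_region(chrom, end, np.iinfo(np.int64).max).n_sites:
            raise ValueError(f"variants on {chrom} fall outside region [{start}, {end})")

    si = variants.sample_index(sample)
    ref_arr = np.frombuffer(reference.upper().encode("ascii"), dtype="S1")
    offsets = local.pos - start
    stated = local.ref.astype("S1")
    mismatch = ref_arr[offsets] != stated
    if mismatch.any():
        j = int(np.nonzero(mismatch)[0][0])
        raise ValueError(
            f"reference mismatch at {chrom}:{start + int(offsets[j]) + 1}: variant "
            f"states ref={stated[j].decode()!r} but sequence has "
            f"{ref_arr[offsets[j]].decode()!r}"
        )

    seqs = []
    for h in (0, 1):
        arr = ref_arr.copy()
        carried = local.haplotypes[:, si, h] == 1
        arr[offsets[carried]] = np.array(
            [a.encode() for a in local.alt[carried]], dtype="S1"
        )
        seqs.append(arr.tobytes().decode("ascii"))
    return HaplotypePair(
        sample=sample, chrom=chrom, start=start, end=end, hap1=seqs[0], hap2=seqs[1]
    )


def read_phased_vcf(path: str, region: str | None = None) -> tuple[list[RawVariant], list[str]]:
    """Parse a (plain or bgzipped) VCF into raw variant records.

    Returns the record list and the sample list.  Genotype phase flags
    are taken from the GT separator.  ``region`` uses samtools syntax
    ("chrom:start-end", 1-based inclusive) and requires an index.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    records = []
    it = vcf(region) if region else vcf
    for v in it:
        gts = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        records.append(
            RawVariant(
                chrom=v.CHROM,
                pos1=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=gts[:, :2].copy(),
                phased=gts[:, 2].astype(bool),
            )
        )
    vcf.close()
    return records, samples


def write_haplotype_fasta(pairs: list[HaplotypePair], path: str, width: int = 80) -> None:
    """Write per-sample haplotype pairs as a two-record-per-sample FASTA."""
    with open(path, "w") as fh:
        for pair in pairs:
            for tag, seq in (("hap1", pair.hap1), ("hap2", pair.hap2)):
                fh.write(f">{pair.sample}_{tag} {pair.chrom}:{pair.start}-{pair.end}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
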