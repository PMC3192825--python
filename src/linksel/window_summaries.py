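"""100 kb window partitioning, masking, and per-window summary statistics.

The genome is tiled with non-overlapping fixed-size windows; windows within
10 Mb of a centromere, telomere, or chromosome end are dropped.  Variants
are filtered to biallelic reference-matching SNPs outside repeat and
conserved-element masks and away from indels/structural variants, and each
window is summarized by its SNP count S, covered bases, human-chimp
difference count d, aligned bases, divergence-normalized diversity
S_norm = (S/covered)/(d/aligned), mean folded MAF, pairwise diversity,
Tajima's D, GC content, and genic fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import merge_intervals

__all__ = [
    "GenomicWindow",
    "WindowSummary",
    "partition_genome",
    "load_vcf",
    "load_bed",
    "ingest_variants",
    "summarize_window",
    "tajimas_d",
    "tajima_constants",
    "cgs_het_filter",
    "classify_window",
    "intervals_overlap_length",
]

WINDOW_SIZE = 100_000
EXCLUSION = 10_000_000


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    recomb_rate: float = float("nan")  # cM/Mb, from an input column

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass
class WindowSummary:
    """All per-window statistics consumed by the correlation suite."""

    chrom: str
    start: int
    end: int
    S: int = 0
    covered: int = 0
    d: float = 0.0
    aligned: int = 0
    S_norm: float = float("nan")
    mean_maf: float = float("nan")
    pi: float = float("nan")
    tajimas_D: float = float("nan")
    gc: float = float("nan")
    genic_frac: float = float("nan")
    recomb_rate: float = float("nan")
    D_N: float = float("nan")
    D_S: float = float("nan")
    L_N: float = float("nan")
    L_S: float = float("nan")
    d_N: float = float("nan")
    d_S: float = float("nan")
    window_class: str = "neither"
    valid: bool = True  # False when S_norm is undefined (covered=0 or d=0)


def intervals_overlap_length(
    intervals: np.ndarray, start: int, end: int
) -> int:
    """Total bases of (merged) ``intervals`` overlapping [start, end)."""
    ivals = merge_intervals(intervals)
    if len(ivals) == 0:
        return 0
    s = np.maximum(ivals[:, 0], start)
    e = np.minimum(ivals[:, 1], end)
    return int(np.maximum(e - s, 0).sum())


def partition_genome(
    chrom_lengths: dict[str, int],
    feature_annotations: pd.DataFrame | None = None,
    window_size: int = WINDOW_SIZE,
    exclusion: int = EXCLUSION,
) -> list[GenomicWindow]:
    """Tile each chromosome with non-overlapping windows, dropping any
    window overlapping an exclusion zone.

    Exclusion zones extend ``exclusion`` bp around every annotated
    centromere/telomere interval and inward from both chromosome ends.
    Trailing partial windows are dropped.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome -> length in bp (must be positive).
    feature_annotations
        Optional BED-like frame with columns ``chrom, start, end`` (and
        optionally ``feature``) marking centromeres/telomeres.
    """
    zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        zones[chrom] = [(0, exclusion), (length - exclusion, length)]
    if feature_annotations is not None:
        required = {"chrom", "start", "end"}
        if not required.issubset(feature_annotations.columns):
            raise ValueError(
                f"annotations need columns {sorted(required)}"
            )
        for i, row in feature_annotations.iterrows():
            chrom = row["chrom"]
            if chrom not in chrom_lengths:
                raise ValueError(f"annotation line {i}: unknown chrom {chrom}")
            s, e = int(row["start"]), int(row["end"])
            if s < 0 or e > chrom_lengths[chrom] or e <= s:
                raise ValueError(
                    f"annotation line {i}: interval [{s},{e}) outside "
                    f"{chrom} bounds"
                )
            zones[chrom].append((s - exclusion, e + exclusion))
    windows: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        zz = merge_intervals(
            np.array([(max(s, 0), min(e, length)) for s, e in zones[chrom]])
        )
        for start in range(0, length - window_size + 1, window_size):
            end = start + window_size
            if intervals_overlap_length(zz, start, end) > 0:
                continue
            windows.append(GenomicWindow(chrom, start, end))
    return windows


def _positions_in(intervals: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the merged intervals."""
    ivals = merge_intervals(intervals)
    if len(ivals) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(ivals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[ok] = pos[ok] < ivals[idx[ok], 1]
    return inside


def load_vcf(path, chrom: str | None = None) -> pd.DataFrame:
    """Read variant records from a VCF into the frame ingest_variants
    expects (0-based ``pos``, ``ref``, comma-joined ``alt``)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if chrom is not None and v.CHROM != chrom:
            continue
        rows.append(
            (v.CHROM, v.POS - 1, v.REF, ",".join(v.ALT) if v.ALT else "")
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def load_bed(path, chrom: str | None = None) -> np.ndarray:
    """Read a BED file into a merged (n, 2) interval array."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if not len(df):
        return np.empty((0, 2), dtype=np.int64)
    return merge_intervals(df[["start", "end"]].to_numpy(dtype=np.int64))


def ingest_variants(
    records: pd.DataFrame,
    repeat_mask: np.ndarray | None = None,
    conserved_mask: np.ndarray | None = None,
    coverage_mask: np.ndarray | None = None,
    sv_positions: np.ndarray | None = None,
    sv_distance: int = 2,
) -> pd.DataFrame:
    """Filter variant records to analysable biallelic SNPs.

    ``records`` must be position-sorted with columns ``pos, ref, alt``
    where ``alt`` holds comma-separated alternate alleles, plus optional
    ``ref_matches`` (bool) asserting one observed allele equals the
    reference.  Retains records that are biallelic SNPs, match the
    reference, fall outside repeat and conserved masks, lie inside the
    coverage mask, and are at least ``sv_distance`` bp from any declared
    indel/SV position (strictly closer sites are removed).
    """
    if not records["pos"].is_monotonic_increasing:
        raise ValueError("variant records must be sorted by position")
    pos = records["pos"].to_numpy()
    keep = np.ones(len(records), dtype=bool)
    alts = records["alt"].astype(str)
    n_alleles = alts.str.count(",") + 2
    keep &= (n_alleles == 2).to_numpy()
    is_snp = (
        (records["ref"].astype(str).str.len() == 1)
        & (alts.str.len() == 1)
    ).to_numpy()
    keep &= is_snp
    if "ref_matches" in records.columns:
        keep &= records["ref_matches"].to_numpy(dtype=bool)
    if repeat_mask is not None:
        keep &= ~_positions_in(repeat_mask, pos)
    if conserved_mask is not None:
        keep &= ~_positions_in(conserved_mask, pos)
    if coverage_mask is not None:
        keep &= _positions_in(coverage_mask, pos)
    if sv_positions is not None and len(sv_positions):
        sv = np.sort(np.asarray(sv_positions))
        i = np.searchsorted(sv, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
        left_ok = i > 0
        dist[left_ok] = np.minimum(dist[left_ok], pos[left_ok] - sv[i[left_ok] - 1])
        right_ok = i < len(sv)
        dist[right_ok] = np.minimum(dist[right_ok], sv[i[right_ok]] - pos[right_ok])
        keep &= dist >= sv_distance
    return records.loc[keep].reset_index(drop=True)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1, a2, b1, b2, c1, c2, e1, e2 constants for sample
    size ``n`` chromosomes."""
    if n < 3:
        raise ValueError("Tajima's D requires n >= 3 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites S, mean pairwise differences pi,
    and sample size n (chromosomes).

    Returns ``nan`` (undefined-statistic signal) when S = 0 or n < 3.
    """
    if S <= 0 or n < 3:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi - S / c["a1"]) / np.sqrt(var))


def cgs_het_filter(
    window_snp_het_counts: Sequence[int],
    min_snps: int = 10,
    het_threshold: float = 3.0,
) -> bool:
    """Heterozygosity outlier rule for 6-diploid genotype data.

    Returns True ("drop the window") iff the window has at least
    ``min_snps`` SNPs and the mean number of heterozygous genotypes per
    SNP (out of 6) strictly exceeds ``het_threshold``.  Such windows are
    collapsed-duplication suspects.
    """
    counts = np.asarray(window_snp_het_counts, dtype=float)
    if counts.size and (counts.min() < 0 or counts.max() > 6):
        raise ValueError("het counts must lie in [0, 6]")
    if counts.size < min_snps:
        return False
    return bool(counts.mean() > het_threshold)


def classify_window(genic_frac: float, genic_threshold: float = 0.5) -> str:
    """Genic / nongenic / neither classification by transcript overlap.

    Non-genic windows have zero transcript overlap; genic windows have at
    least ``genic_threshold`` of their bases in a transcript; everything in
    between belongs to neither group and is excluded from the contrast.
    """
    if not (0 <= genic_frac <= 1):
        raise ValueError("genic_frac must lie in [0, 1]")
    if genic_frac == 0:
        return "nongenic"
    if genic_frac >= genic_threshold:
        return "genic"
    return "neither"


def _pairwise_pi(genotypes: np.ndarray) -> float:
    """Mean pairwise differences from a (sites x chromosomes) 0/1 matrix."""
    n = genotypes.shape[1]
    if n < 2:
        return float("nan")
    k = genotypes.sum(axis=1)
    return float(np.sum(k * (n - k)) / (n * (n - 1) / 2.0))


def summarize_window(
    window: GenomicWindow,
    snp_pos: np.ndarray,
    snp_maf: np.ndarray,
    coverage: np.ndarray,
    hc_diff_pos: np.ndarray,
    aligned: np.ndarray,
    transcripts: np.ndarray | None = None,
    gc_flags: np.ndarray | None = None,
    haplotypes: np.ndarray | None = None,
    sample_size: int | None = None,
    raw_d_denominator: bool = False,
) -> WindowSummary:
    """Compute one window's summary statistics.

    All inputs are assumed pre-filtered by :func:`ingest_variants`
    conventions (masked SNPs and masked human-chimp differences removed;
    masked bases absent from ``coverage``/``aligned``).

    Parameters
    ----------
    snp_pos, snp_maf
        Positions and folded MAFs of retained SNPs (whole chromosome).
    coverage
        Intervals of bases with sequencing coverage after masks.
    hc_diff_pos
        Positions of retained human-chimp differences.
    aligned
        Intervals of bases counted for divergence (aligned, unmasked).
    gc_flags
        Optional boolean per-included-base G/C flags as ``(positions,
        is_gc)`` arrays: tuple of two arrays.  GC is computed over bases
        meeting the inclusion criteria.
    haplotypes
        Optional (sites x chromosomes) 0/1 matrix for the window's SNPs,
        used for pi and Tajima's D.
    raw_d_denominator
        When True, S_norm uses the literal raw difference count
        (S/covered)/d instead of the aligned-base-normalized form.
    """
    w = window
    in_w = (snp_pos >= w.start) & (snp_pos < w.end)
    S = int(in_w.sum())
    covered = intervals_overlap_length(coverage, w.start, w.end)
    d = float(((hc_diff_pos >= w.start) & (hc_diff_pos < w.end)).sum())
    aligned_n = intervals_overlap_length(aligned, w.start, w.end)
    out = WindowSummary(
        chrom=w.chrom, start=w.start, end=w.end,
        S=S, covered=covered, d=d, aligned=aligned_n,
        recomb_rate=w.recomb_rate,
    )
    if covered > 0 and d > 0:
        if raw_d_denominator:
            out.S_norm = (S / covered) / d
        else:
            out.S_norm = (S / covered) / (d / aligned_n)
    else:
        # Undefined normalization: flag the window out of correlation input.
        out.S_norm = float("nan")
        out.valid = False
    if S > 0:
        out.mean_maf = float(snp_maf[in_w].mean())
    if transcripts is not None:
        out.genic_frac = intervals_overlap_length(
            transcripts, w.start, w.end
        ) / (w.end - w.start)
        out.window_class = classify_window(out.genic_frac)
    if gc_flags is not None:
        gpos, is_gc = gc_flags
        sel = (gpos >= w.start) & (gpos < w.end)
        if sel.any():
            out.gc = float(np.asarray(is_gc)[sel].mean())
    if haplotypes is not None and haplotypes.size:
        n = haplotypes.shape[1] if sample_size is None else sample_size
        out.pi = _pairwise_pi(haplotypes)
        out.tajimas_D = tajimas_d(haplotypes.shape[0], out.pi, n)
    return out
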