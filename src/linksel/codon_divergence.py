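"""Nei-Gojobori synonymous/nonsynonymous site counting and difference
classification for human-chimp coding divergence.

Each codon position contributes a synonymous-site fraction equal to the
share of its three possible single-base changes that preserve the amino
acid; sites are counted from the human (reference) sequence only.  Observed
human-chimp differences are classified one site at a time, holding the
other two codon positions at the human alleles.  Per-window totals give
``D_N``, ``D_S``, ``L_N``, ``L_S`` and the per-site rates ``d_N = D_N/L_N``
and ``d_S = D_S/L_S``.  No multiple-hit correction is applied: the rates
are raw proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "BASES",
    "CodingAnnotation",
    "DivergenceCounts",
    "translate_codon",
    "syn_fraction",
    "count_sites",
    "classify_difference",
    "window_dnds",
]

BASES = "ACGT"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Translate a DNA codon with the standard genetic code; ``*`` for stop."""
    codon = codon.upper()
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


class InternalStopWarning(UserWarning):
    """Raised (as a warning) when a CDS codon is a stop codon mid-sequence."""


@dataclass(frozen=True)
class CodingAnnotation:
    """A single resolved gene model: CDS intervals on one chromosome.

    Intervals are 0-based half-open genomic coordinates in transcription
    order; ``strand`` is ``"+"`` or ``"-"``.  Overlapping models are expected
    to have been resolved upstream to one (the longest) model per locus.
    """

    chrom: str
    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    name: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class DivergenceCounts:
    """Per-window Nei-Gojobori tallies.

    ``d_N``/``d_S`` are ``nan`` when the corresponding site count is zero.
    """

    D_N: float = 0.0
    D_S: float = 0.0
    L_N: float = 0.0
    L_S: float = 0.0

    @property
    def d_N(self) -> float:
        return self.D_N / self.L_N if self.L_N > 0 else float("nan")

    @property
    def d_S(self) -> float:
        return self.D_S / self.L_S if self.L_S > 0 else float("nan")


def syn_fraction(codon: str, position: int) -> float:
    """Fraction of the 3 possible single-base changes at ``position`` of
    ``codon`` that are synonymous.

    Changes to or from stop codons are treated as nonsynonymous.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    n_syn = 0
    for b in BASES:
        if b == codon[position]:
            continue
        mutant = codon[:position] + b + codon[position + 1 :]
        if translate_codon(mutant) == aa:
            n_syn += 1
    return n_syn / 3.0


def count_sites(
    cds: str,
    eligibility_mask: Sequence[bool] | None = None,
) -> tuple[float, float]:
    """Count nonsynonymous (L_N) and synonymous (L_S) sites in a CDS.

    Parameters
    ----------
    cds
        In-frame coding sequence (length divisible by 3), human reference.
    eligibility_mask
        Optional per-base boolean flags (True = count this base).  Masked
        bases contribute 0 to both totals; the codon context still uses the
        full human codon.

    Returns
    -------
    (L_N, L_S)
        Site counts; ``L_N + L_S`` equals 3x the number of fully eligible,
        non-stop codons (fractional codons contribute proportionally).

    Codons containing an internal stop are skipped with a warning, as are
    codons containing ambiguous bases.
    """
    cds = str(cds).upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    if eligibility_mask is None:
        mask = np.ones(len(cds), dtype=bool)
    else:
        mask = np.asarray(eligibility_mask, dtype=bool)
        if mask.shape != (len(cds),):
            raise ValueError("eligibility mask length must equal CDS length")
    L_N = 0.0
    L_S = 0.0
    n_codons = len(cds) // 3
    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        if any(b not in BASES for b in codon):
            continue
        if translate_codon(codon) == "*":
            if c < n_codons - 1:
                warnings.warn(
                    f"internal stop codon {codon} at codon {c}; skipped",
                    InternalStopWarning,
                    stacklevel=2,
                )
            continue
        for p in range(3):
            if not mask[3 * c + p]:
                continue
            fs = syn_fraction(codon, p)
            L_S += fs
            L_N += 1.0 - fs
    return L_N, L_S


def classify_difference(
    codon_human: str, position_in_codon: int, chimp_base: str
) -> str:
    """Classify a single human-chimp difference within one codon.

    The other two codon positions are held at the human alleles.  Returns
    ``"synonymous"``, ``"nonsynonymous"`` or ``"none"`` (identical base).
    Changes creating or destroying a stop codon are nonsynonymous.  Sites
    with ambiguous bases raise ``ValueError`` (callers skip them).
    """
    codon_human = codon_human.upper()
    chimp_base = chimp_base.upper()
    if position_in_codon not in (0, 1, 2):
        raise ValueError("position_in_codon must be 0, 1 or 2")
    if chimp_base not in BASES or any(b not in BASES for b in codon_human):
        raise ValueError(f"ambiguous base in {codon_human}->{chimp_base}")
    if codon_human[position_in_codon] == chimp_base:
        return "none"
    mutant = (
        codon_human[:position_in_codon]
        + chimp_base
        + codon_human[position_in_codon + 1 :]
    )
    if translate_codon(codon_human) == translate_codon(mutant):
        return "synonymous"
    return "nonsynonymous"


def _cds_positions(annotation: CodingAnnotation) -> np.ndarray:
    """Genomic positions of CDS bases in reading-frame order."""
    pos = np.concatenate(
        [np.arange(s, e) for s, e in annotation.intervals]
    ) if annotation.intervals else np.empty(0, dtype=int)
    if annotation.strand == "-":
        pos = pos[::-1]
    return pos


def window_dnds(
    windows: Iterable[tuple[str, int, int]],
    annotations: Sequence[CodingAnnotation],
    genome: dict[str, str],
    hc_diffs: pd.DataFrame,
    repeat_mask: dict[str, np.ndarray] | None = None,
    aligned_mask: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-window D_N, D_S, L_N, L_S, d_N, d_S.

    Parameters
    ----------
    windows
        ``(chrom, start, end)`` triples, 0-based half-open.
    annotations
        Resolved coding models (one per locus; minus-strand models are
        reverse-complemented internally).
    genome
        Human reference sequence per chromosome.
    hc_diffs
        DataFrame with columns ``chrom, pos, human_base, chimp_base``
        (0-based positions); already restricted to aligned, non-repeat
        bases by the caller's ingestion step if those masks are not given.
    repeat_mask, aligned_mask
        Optional per-chromosome boolean arrays (True = repeat-masked /
        True = aligned).  Sites failing the masks contribute to neither
        site counts nor difference counts.  Conserved-element masks are
        deliberately NOT applied to coding divergence.
    """
    results = []
    diffs_by_chrom = {c: g for c, g in hc_diffs.groupby("chrom")}
    for chrom, start, end in windows:
        counts = DivergenceCounts()
        for ann in annotations:
            if ann.chrom != chrom:
                continue
            pos = _cds_positions(ann)
            if pos.size == 0 or len(pos) % 3 != 0:
                continue
            in_window = (pos >= start) & (pos < end)
            if not in_window.any():
                continue
            seq = genome[chrom]
            cds = "".join(seq[p] for p in pos)
            if ann.strand == "-":
                cds = str(Seq(cds).complement())
            eligible = in_window.copy()
            if repeat_mask is not None and chrom in repeat_mask:
                eligible &= ~repeat_mask[chrom][pos]
            if aligned_mask is not None and chrom in aligned_mask:
                eligible &= aligned_mask[chrom][pos]
            L_N, L_S = count_sites(cds, eligible)
            counts.L_N += L_N
            counts.L_S += L_S
            # Classify differences falling in this model and window.
            dd = diffs_by_chrom.get(chrom)
            if dd is None:
                continue
            pos_to_idx = {int(p): i for i, p in enumerate(pos)}
            for _, row in dd.iterrows():
                i = pos_to_idx.get(int(row["pos"]))
                if i is None or not eligible[i]:
                    continue
                codon_i = i // 3
                codon = cds[3 * codon_i : 3 * codon_i + 3]
                hb, cb = str(row["human_base"]), str(row["chimp_base"])
                if ann.strand == "-":
                    hb = str(Seq(hb).complement())
                    cb = str(Seq(cb).complement())
                try:
                    if translate_codon(codon) == "*":
                        continue
                    cls = classify_difference(codon, i % 3, cb)
                except (ValueError, KeyError):
                    continue
                if cls == "nonsynonymous":
                    counts.D_N += 1
                elif cls == "synonymous":
                    counts.D_S += 1
        results.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "D_N": counts.D_N,
                "D_S": counts.D_S,
                "L_N": counts.L_N,
                "L_S": counts.L_S,
                "d_N": counts.d_N,
                "d_S": counts.d_S,
            }
        )
    return pd.DataFrame(results)
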