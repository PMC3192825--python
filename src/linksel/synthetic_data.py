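"""Synthetic inputs with known ground truth for every pipeline stage.

Generators here emulate (i) pileup read counts from ~2,000 low-coverage
individuals with a uniform-miscall sequencing error model, (ii) BED-style
repeat/conserved/coverage/transcript masks, (iii) per-window genomic
feature tables with a tunable Gaussian-copula correlation structure, and
(iv) paired human/chimp coding sequences with planted synonymous and
nonsynonymous differences.  Each generator's ground truth is recoverable by
the matching downstream estimator, which is how the pipeline is tested
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_divergence import BASES, translate_codon

__all__ = [
    "PileupPanel",
    "SyntheticWindowTable",
    "MaskSet",
    "gen_pileups",
    "gen_window_table",
    "gen_masks",
    "gen_cds_alignment",
    "write_fasta_pair",
]


# ---------------------------------------------------------------------------
# Pileups


@dataclass
class PileupPanel:
    """Per-site, per-individual base counts for low-coverage MAF estimation.

    ``counts`` has shape ``(n_sites, n_ind, 4)`` over bases A,C,G,T.
    ``q_true`` is the planted population minor allele frequency per site,
    ``e`` the per-read miscall probability (a miscall substitutes one of the
    other three bases uniformly).  ``major_idx``/``minor_idx`` record which
    base indexes carry the planted major/minor alleles.
    """

    counts: np.ndarray
    q_true: np.ndarray
    e: float
    n_ind: int
    major_idx: np.ndarray
    minor_idx: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        if np.any((self.q_true < 0) | (self.q_true > 0.5)):
            raise ValueError("q_true must lie in [0, 0.5]")
        if not (0 <= self.e < 0.75):
            raise ValueError("error rate e must lie in [0, 0.75)")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    def pooled_counts(self) -> np.ndarray:
        """Base counts summed over individuals, shape (n_sites, 4)."""
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: site, individual, countA..countT, e."""
        n_sites, n_ind, _ = self.counts.shape
        site = np.repeat(np.arange(n_sites), n_ind)
        ind = np.tile(np.arange(n_ind), n_sites)
        flat = self.counts.reshape(n_sites * n_ind, 4)
        keep = flat.sum(axis=1) > 0
        df = pd.DataFrame(
            {
                "site": site[keep],
                "individual": ind[keep],
                "countA": flat[keep, 0],
                "countC": flat[keep, 1],
                "countG": flat[keep, 2],
                "countT": flat[keep, 3],
                "e": self.e,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupPanel":
        df = pd.read_csv(path, sep="\t")
        n_sites = int(df["site"].max()) + 1
        n_ind = int(df["individual"].max()) + 1
        counts = np.zeros((n_sites, n_ind, 4), dtype=np.int64)
        cols = df[["countA", "countC", "countG", "countT"]].to_numpy()
        counts[df["site"].to_numpy(), df["individual"].to_numpy()] = cols
        pooled = counts.sum(axis=1)
        order = np.argsort(-pooled, axis=1, kind="stable")
        return cls(
            counts=counts,
            q_true=np.full(n_sites, np.nan),
            e=float(df["e"].iloc[0]) if len(df) else 0.0,
            n_ind=n_ind,
            major_idx=order[:, 0],
            minor_idx=order[:, 1],
        )


def gen_pileups(
    q_true: Sequence[float],
    depth_law: Callable[[np.random.Generator, int], np.ndarray] | float,
    e: float = 0.01,
    n_ind: int = 2000,
    ploidy: int = 2,
    seed: int = 0,
) -> PileupPanel:
    """Simulate per-individual read counts at sites with known MAF.

    Genotypes are drawn under Hardy-Weinberg at minor allele frequency
    ``q_true``; each individual contributes ``depth`` reads drawn uniformly
    from its two chromosomes, and each read is miscalled with probability
    ``e`` to one of the other three bases uniformly.

    Parameters
    ----------
    q_true
        Planted population minor allele frequencies, one per site, in
        [0, 0.5].
    depth_law
        Either a callable ``(rng, n) -> int array`` of per-individual read
        depths, or a float giving the mean of a Poisson depth distribution
        (e.g. 0.05 for 0.05x coverage per individual at this site).
    """
    q = np.asarray(q_true, dtype=float)
    if np.any((q < 0) | (q > 0.5)):
        raise ValueError("q_true must lie in [0, 0.5]")
    if not (0 <= e < 0.75):
        raise ValueError("error rate e must lie in [0, 0.75)")
    if ploidy != 2:
        raise ValueError("only diploid individuals are supported")
    rng = np.random.default_rng(seed)
    n_sites = len(q)
    counts = np.zeros((n_sites, n_ind, 4), dtype=np.int64)
    # Random distinct major/minor base identities per site.
    major_idx = rng.integers(0, 4, size=n_sites)
    minor_idx = (major_idx + rng.integers(1, 4, size=n_sites)) % 4
    for s in range(n_sites):
        geno = rng.binomial(2, q[s], size=n_ind)  # minor-allele dosage
        if callable(depth_law):
            depth = np.asarray(depth_law(rng, n_ind), dtype=np.int64)
        else:
            depth = rng.poisson(float(depth_law), size=n_ind)
        if np.any(depth < 0):
            raise ValueError("depth_law produced negative depths")
        # P(read carries minor allele) = dosage/2; then uniform miscall.
        minor_reads = rng.binomial(depth, geno / 2.0)
        major_reads = depth - minor_reads
        for reads, true_idx in (
            (major_reads, major_idx[s]),
            (minor_reads, minor_idx[s]),
        ):
            errs = rng.binomial(reads, e)
            counts[s, :, true_idx] += reads - errs
            # Miscalls go uniformly to the other three bases.
            if errs.sum():
                others = [b for b in range(4) if b != true_idx]
                split = rng.multinomial(1, [1 / 3] * 3, size=errs.sum())
                per_ind = np.repeat(np.arange(n_ind), errs)
                for j, b in enumerate(others):
                    np.add.at(counts[s, :, b], per_ind, split[:, j])
    return PileupPanel(
        counts=counts,
        q_true=q,
        e=e,
        n_ind=n_ind,
        major_idx=major_idx,
        minor_idx=minor_idx,
    )


# ---------------------------------------------------------------------------
# Window feature tables (Gaussian copula)


@dataclass
class SyntheticWindowTable:
    """Per-window genomic features with a known rank-correlation structure."""

    table: pd.DataFrame
    copula: np.ndarray
    columns: tuple[str, ...]
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


DEFAULT_MARGINALS: dict[str, stats.rv_continuous | stats.rv_discrete] = {
    # Recombination rates in cM/Mb: right-skewed, median near 1.
    "recomb_rate": stats.lognorm(s=0.9, scale=1.1),
    "gc": stats.beta(a=38, b=55),  # GC fraction centred near 0.41
    "genic_frac": stats.beta(a=0.45, b=0.9),
    "divergence": stats.poisson(mu=1200.0),  # hc differences per window
    "snp_count": stats.poisson(mu=80.0),
    "covered": stats.binom(n=100_000, p=0.35),
    "mean_maf": stats.beta(a=8, b=24),
}


def gaussian_copula_spearman(pearson_rho: float) -> float:
    """Spearman rank correlation implied by a Gaussian copula with latent
    Pearson correlation ``pearson_rho``: (6/pi) asin(rho/2)."""
    return 6.0 / np.pi * np.arcsin(pearson_rho / 2.0)


def gen_window_table(
    n_windows: int,
    copula: np.ndarray | None = None,
    marginals: dict[str, object] | None = None,
    seed: int = 0,
) -> SyntheticWindowTable:
    """Sample a window feature table from a Gaussian copula.

    Latent normals with correlation matrix ``copula`` are mapped through
    their CDF and then through each feature's marginal quantile function,
    so the rank correlations between columns converge to
    ``(6/pi) asin(rho/2)`` for continuous marginals.
    """
    marginals = dict(DEFAULT_MARGINALS if marginals is None else marginals)
    cols = tuple(marginals)
    k = len(cols)
    if copula is None:
        copula = np.eye(k)
    copula = np.asarray(copula, dtype=float)
    if copula.shape != (k, k):
        raise ValueError(
            f"copula shape {copula.shape} does not match {k} features"
        )
    if not np.allclose(copula, copula.T):
        raise ValueError("copula matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(copula)
    if eigvals.min() < -1e-10:
        raise ValueError("copula matrix must be positive semi-definite")
    rng = np.random.default_rng(seed)
    if n_windows == 0:
        table = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
        return SyntheticWindowTable(table, copula, cols, seed)
    z = rng.multivariate_normal(
        np.zeros(k), copula, size=n_windows, method="eigh"
    )
    u = stats.norm.cdf(z)
    data = {}
    for j, c in enumerate(cols):
        dist = marginals[c]
        data[c] = dist.ppf(u[:, j])
    table = pd.DataFrame(data)
    return SyntheticWindowTable(table, copula, cols, seed)


# ---------------------------------------------------------------------------
# Masks


@dataclass
class MaskSet:
    """BED-style interval sets for one window, 0-based half-open.

    ``coverage`` marks bases with sequencing data; ``repeats`` and
    ``conserved`` mark bases to exclude; ``transcripts`` mark genic bases.
    """

    window: tuple[int, int]
    repeats: np.ndarray
    conserved: np.ndarray
    coverage: np.ndarray
    transcripts: np.ndarray

    def to_bed(self, directory: str | Path, chrom: str = "chrSim") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("repeats", "conserved", "coverage", "transcripts"):
            ivals = getattr(self, name)
            with open(directory / f"{name}.bed", "w") as fh:
                for s, e in ivals:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Normalize possibly-overlapping half-open intervals: sort and merge."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ivals = np.asarray(intervals, dtype=np.int64)
    ivals = ivals[np.argsort(ivals[:, 0], kind="stable")]
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _block_mask(
    rng: np.random.Generator,
    start: int,
    end: int,
    frac: float,
    block: int,
) -> np.ndarray:
    """Mask whole blocks of length ``block`` independently with prob frac."""
    if frac <= 0:
        return np.empty((0, 2), dtype=np.int64)
    if frac >= 1:
        return np.array([[start, end]], dtype=np.int64)
    edges = np.arange(start, end, block)
    hit = rng.random(len(edges)) < frac
    ivals = [
        (s, min(s + block, end)) for s, keep in zip(edges, hit) if keep
    ]
    return merge_intervals(np.asarray(ivals, dtype=np.int64).reshape(-1, 2))


def gen_masks(
    window: tuple[int, int],
    repeat_frac: float = 0.45,
    conserved_frac: float = 0.05,
    coverage_frac: float = 0.35,
    gene_layout: Sequence[tuple[int, int]] | float | None = 0.3,
    block: int = 500,
    seed: int = 0,
) -> MaskSet:
    """Generate repeat/conserved/coverage/transcript masks for one window.

    Fractions follow a block model: the window is tiled with ``block``-bp
    tiles, each masked independently, so the realized masked fraction is
    binomial around the request.  ``gene_layout`` may be explicit intervals
    or a target genic fraction (a single contiguous transcript is placed).
    """
    for name, frac in (
        ("repeat_frac", repeat_frac),
        ("conserved_frac", conserved_frac),
        ("coverage_frac", coverage_frac),
    ):
        if not (0 <= frac <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    start, end = map(int, window)
    if end <= start:
        raise ValueError("window end must exceed start")
    rng = np.random.default_rng(seed)
    repeats = _block_mask(rng, start, end, repeat_frac, block)
    conserved = _block_mask(rng, start, end, conserved_frac, block)
    coverage = _block_mask(rng, start, end, coverage_frac, block)
    if gene_layout is None:
        transcripts = np.empty((0, 2), dtype=np.int64)
    elif isinstance(gene_layout, (int, float)):
        g = float(gene_layout)
        if not (0 <= g <= 1):
            raise ValueError("genic fraction must lie in [0, 1]")
        length = int(round(g * (end - start)))
        if length == 0:
            transcripts = np.empty((0, 2), dtype=np.int64)
        else:
            s = int(rng.integers(start, end - length + 1))
            transcripts = np.array([[s, s + length]], dtype=np.int64)
    else:
        transcripts = merge_intervals(np.asarray(gene_layout))
    return MaskSet(
        window=(start, end),
        repeats=repeats,
        conserved=conserved,
        coverage=coverage,
        transcripts=transcripts,
    )


# ---------------------------------------------------------------------------
# CDS pairs with planted divergence


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Random in-frame CDS with no stop codons."""
    sense = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if translate_codon(a + b + c) != "*"
    ]
    return [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]


def _single_base_changes(codon: str) -> list[tuple[int, str, str]]:
    """All (position, new_base, class) single-base changes of a codon."""
    out = []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            mutant = codon[:p] + b + codon[p + 1 :]
            if translate_codon(mutant) == "*":
                continue  # keep both sequences stop-free
            cls = (
                "synonymous"
                if translate_codon(mutant) == translate_codon(codon)
                else "nonsynonymous"
            )
            out.append((p, b, cls))
    return out


def gen_cds_alignment(
    n_codons: int,
    n_syn_diffs: int,
    n_nonsyn_diffs: int,
    seed: int = 0,
) -> tuple[str, str]:
    """Paired human/chimp CDS with exact planted difference counts.

    Each planted difference occupies its own codon (one substitution per
    codon), so downstream per-site classification recovers exactly
    ``n_syn_diffs`` synonymous and ``n_nonsyn_diffs`` nonsynonymous
    differences.  Neither sequence contains a premature stop codon.

    Raises
    ------
    ValueError
        If the request is infeasible (more differences than codons able to
        host them).
    """
    if n_syn_diffs < 0 or n_nonsyn_diffs < 0 or n_codons <= 0:
        raise ValueError("counts must be non-negative, n_codons positive")
    if n_syn_diffs + n_nonsyn_diffs > n_codons:
        raise ValueError(
            f"cannot place {n_syn_diffs + n_nonsyn_diffs} single-site "
            f"differences in {n_codons} codons (one per codon)"
        )
    rng = np.random.default_rng(seed)
    human = _random_cds(rng, n_codons)
    chimp = list(human)
    order = rng.permutation(n_codons)
    need = [("synonymous", n_syn_diffs), ("nonsynonymous", n_nonsyn_diffs)]
    used: set[int] = set()
    for cls, n_need in need:
        placed = 0
        for c in order:
            if placed == n_need:
                break
            if c in used:
                continue
            options = [
                (p, b) for p, b, k in _single_base_changes(human[c]) if k == cls
            ]
            if not options:
                continue
            p, b = options[int(rng.integers(0, len(options)))]
            chimp[c] = human[c][:p] + b + human[c][p + 1 :]
            used.add(c)
            placed += 1
        if placed < n_need:
            raise ValueError(
                f"could not place {n_need} {cls} differences in "
                f"{n_codons} codons"
            )
    return "".join(human), "".join(chimp)


def write_fasta_pair(
    human: str, chimp: str, path: str | Path, names: tuple[str, str] = ("human", "chimp")
) -> None:
    """Write the paired CDS as a two-record FASTA file."""
    with open(path, "w") as fh:
        for name, seq in zip(names, (human, chimp)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
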