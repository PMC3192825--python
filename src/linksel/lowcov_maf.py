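"""Population minor-allele-frequency estimation from low-coverage read counts.

Sites covered by at least a fixed number of reads (default 100, pooled over
all individuals) are downsampled to that cap, a fast method-of-moments MAF
estimate is computed from the pooled base counts, and sites passing a 1%
prefilter receive a per-individual binomial maximum-likelihood estimate
under Hardy-Weinberg genotype frequencies.  Sites whose ML estimate exceeds
5% are called SNPs.  No per-individual genotypes are ever called: with
~0.05 reads per individual per site the read counts themselves carry all
the usable frequency information.

The error model is a uniform miscall: a read reports one of the other three
bases with total probability ``e``.  Under this model the expected minor
base read fraction is ``f = q(1-e) + (1-q) e/3``, whose inversion gives the
method-of-moments estimator; the per-read minor-base probabilities given
minor-allele dosage g in {0,1,2} are ``p_0 = e/3``, ``p_1 = 1/2 - e/3``,
``p_2 = 1 - e``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

__all__ = [
    "MAFEstimate",
    "SiteSkipped",
    "downsample_site",
    "mom_maf",
    "ml_maf",
    "call_snps",
    "estimate_panel",
]

DEPTH_CAP = 100
PREFILTER = 0.01
SNP_THRESHOLD = 0.05

_BASE_ORDER = "ACGT"


class SiteSkipped(Exception):
    """Signal (not an error) that a site lacks the read depth to estimate."""


@dataclass
class MAFEstimate:
    """One site's MAF estimates and SNP call."""

    site: int
    mom_estimate: float
    ml_estimate: float | None
    minor_base: str
    depth_used: int
    is_snp: bool
    minor_tie: bool = False


def downsample_site(
    counts: np.ndarray, cap: int = DEPTH_CAP, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Retain exactly ``cap`` reads, sampled uniformly without replacement
    across all reads at the site; individual-of-origin labels preserved.

    Parameters
    ----------
    counts
        Per-individual base counts, shape ``(n_ind, 4)``.
    cap
        Number of reads to retain.

    Returns
    -------
    Reduced per-individual counts with total exactly ``cap``.

    Raises
    ------
    SiteSkipped
        If the site has fewer than ``cap`` reads in total (such sites are
        excluded from frequency estimation upstream).
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < cap:
        raise SiteSkipped(f"site has {total} < {cap} reads")
    if total == cap:
        return counts.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flat = counts.ravel()
    # Multivariate hypergeometric draw over (individual, base) cells.
    kept = rng.multivariate_hypergeometric(flat, cap)
    return kept.reshape(counts.shape)


def mom_maf(base_counts: Sequence[int], e: float = 0.0) -> tuple[float, str, bool]:
    """Method-of-moments MAF from pooled base counts.

    Inverts ``E[f] = q(1-e) + (1-q) e/3`` where ``f`` is the read fraction
    of the second-most common base, clamping the result to [0, 0.5].

    Returns ``(q_hat, minor_base, tie_flag)``; the minor base is the
    second-most common base with ties broken in the fixed order A<C<G<T.
    """
    if e >= 0.75 or e < 0:
        raise ValueError("error rate e must lie in [0, 0.75)")
    counts = np.asarray(base_counts, dtype=np.int64)
    if counts.shape != (4,) or np.any(counts < 0):
        raise ValueError("base_counts must be 4 non-negative integers")
    total = counts.sum()
    if total <= 0:
        raise ValueError("base_counts must sum to a positive total")
    order = np.argsort(-counts, kind="stable")  # stable => A<C<G<T tie-break
    minor_i = order[1]
    tie = bool(
        counts[order[1]] == counts[order[2]]
        or counts[order[0]] == counts[order[1]]
    )
    f = counts[minor_i] / total
    q = (f - e / 3.0) / (1.0 - 4.0 * e / 3.0)
    return float(np.clip(q, 0.0, 0.5)), _BASE_ORDER[minor_i], tie


def _genotype_read_probs(e: float) -> np.ndarray:
    """P(read shows minor base | minor dosage g) for g = 0, 1, 2."""
    return np.array([e / 3.0, 0.5 - e / 3.0, 1.0 - e])


def _loglik(q: float, k: np.ndarray, n: np.ndarray, e: float) -> float:
    """Log-likelihood of per-individual minor read counts k out of n.

    Sums the three Hardy-Weinberg genotypes per individual; binomial
    coefficients are constant in q and omitted.
    """
    p = _genotype_read_probs(e)
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    # per-individual likelihood: sum_g hwe[g] * p[g]^k * (1-p[g])^(n-k);
    # xlogy keeps 0*log(0) = 0 so e = 0 and q at the boundary are exact
    terms = (
        np.log(hwe + 1e-300)[None, :]
        + xlogy(k[:, None], p[None, :])
        + xlogy((n - k)[:, None], 1.0 - p[None, :])
    )
    m = terms.max(axis=1)
    return float(np.sum(m + np.log(np.exp(terms - m[:, None]).sum(axis=1))))


def ml_maf(
    panel: np.ndarray,
    e: float = 0.0,
    minor_idx: int | None = None,
    grid: int = 512,
    tol: float = 1e-6,
    fold: bool = True,
) -> float:
    """Maximum-likelihood MAF for one site from per-individual base counts.

    Parameters
    ----------
    panel
        Per-individual base counts, shape ``(n_ind, 4)``; individuals with
        zero reads contribute nothing.
    e
        Per-read miscall probability.
    minor_idx
        Index of the minor base; defaults to the second-most common base
        pooled over individuals (ties broken A<C<G<T).
    grid
        Number of coarse grid points scanned before local refinement; the
        likelihood can be bimodal near the fold point, so a global scan
        precedes the golden-section polish.

    Returns
    -------
    The frequency q maximizing the Hardy-Weinberg binomial likelihood,
    folded onto [0, 0.5] unless ``fold=False`` (the unfolded estimate is
    useful for bias assessment at the q = 0.5 fold point, where folding
    necessarily biases any estimator downward).
    """
    if e >= 0.75 or e < 0:
        raise ValueError("error rate e must lie in [0, 0.75)")
    panel = np.asarray(panel, dtype=np.int64)
    if panel.ndim != 2 or panel.shape[1] != 4:
        raise ValueError("panel must have shape (n_ind, 4)")
    n = panel.sum(axis=1)
    keep = n > 0
    if not keep.any():
        raise SiteSkipped("empty panel: no reads at site")
    panel = panel[keep]
    n = n[keep]
    if minor_idx is None:
        pooled = panel.sum(axis=0)
        minor_idx = int(np.argsort(-pooled, kind="stable")[1])
    k = panel[:, minor_idx]

    def neg(q: float) -> float:
        return -_loglik(q, k, n, e)

    qs = np.linspace(0.0, 1.0, grid)
    vals = np.array([neg(q) for q in qs])
    j = int(np.argmin(vals))
    lo = qs[max(j - 1, 0)]
    hi = qs[min(j + 1, grid - 1)]
    if hi > lo:
        res = minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": tol}
        )
        q_hat = float(res.x) if res.fun <= vals[j] else float(qs[j])
    else:
        q_hat = float(qs[j])
    return min(q_hat, 1.0 - q_hat) if fold else q_hat


def call_snps(
    panel_counts: Iterable[tuple[int, np.ndarray]],
    e: float = 0.0,
    cap: int = DEPTH_CAP,
    prefilter: float = PREFILTER,
    threshold: float = SNP_THRESHOLD,
    seed: int = 0,
) -> list[MAFEstimate]:
    """Two-stage SNP calling over a stream of sites.

    For each ``(site_id, per-individual counts)`` pair: downsample to the
    read cap, compute the method-of-moments MAF, and only when it exceeds
    ``prefilter`` compute the ML estimate; a site is a SNP when the ML
    estimate strictly exceeds ``threshold``.  Sites below the depth cap are
    silently skipped.
    """
    rng = np.random.default_rng(seed)
    out: list[MAFEstimate] = []
    for site, counts in panel_counts:
        try:
            reduced = downsample_site(counts, cap=cap, seed=rng)
        except SiteSkipped:
            continue
        pooled = reduced.sum(axis=0)
        q_mom, minor_base, tie = mom_maf(pooled, e)
        minor_idx = _BASE_ORDER.index(minor_base)
        if q_mom > prefilter:
            q_ml = ml_maf(reduced, e, minor_idx=minor_idx)
            is_snp = q_ml > threshold
        else:
            q_ml = None
            is_snp = False
        out.append(
            MAFEstimate(
                site=site,
                mom_estimate=q_mom,
                ml_estimate=q_ml,
                minor_base=minor_base,
                depth_used=int(pooled.sum()),
                is_snp=is_snp,
                minor_tie=tie,
            )
        )
    return out


def estimate_panel(
    counts: np.ndarray,
    e: float = 0.0,
    cap: int = DEPTH_CAP,
    prefilter: float = PREFILTER,
    threshold: float = SNP_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Vector convenience wrapper: run :func:`call_snps` over a
    ``(n_sites, n_ind, 4)`` count array and return a tidy DataFrame."""
    stream = ((s, counts[s]) for s in range(counts.shape[0]))
    ests = call_snps(
        stream, e=e, cap=cap, prefilter=prefilter, threshold=threshold, seed=seed
    )
    return pd.DataFrame(
        {
            "site": [x.site for x in ests],
            "mom_maf": [x.mom_estimate for x in ests],
            "ml_maf": [
                np.nan if x.ml_estimate is None else x.ml_estimate for x in ests
            ],
            "minor_base": [x.minor_base for x in ests],
            "depth_used": [x.depth_used for x in ests],
            "is_snp": [x.is_snp for x in ests],
            "minor_tie": [x.minor_tie for x in ests],
        }
    )
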