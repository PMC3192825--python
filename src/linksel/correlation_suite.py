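"""Spearman and partial Spearman correlations over genomic windows, with
permutation tests, bootstrap confidence intervals, percentile subsetting,
and binning for display.

Partial rank correlations are computed from the precision matrix of the
Spearman correlation matrix of all involved columns, which for a single
control reduces to the familiar first-order formula
``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` on ranks.  The
genic-versus-non-genic contrast uses a label permutation that preserves
group sizes; p-values use the add-one convention by default so they are
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "PermutationTestResult",
    "spearman",
    "partial_spearman",
    "genic_permutation_test",
    "bootstrap_ci",
    "subset_by_percentile",
    "bin_windows",
]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_windows: int
    controlled_variables: tuple[str, ...] = ()
    method: str = "pairwise"

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


@dataclass
class PermutationTestResult:
    observed_diff: float
    n_perm: int
    p_value: float
    p_value_proportion: float
    seed: int


def _complete(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    ok = np.ones(len(arrs[0]), dtype=bool)
    for a in arrs:
        ok &= np.isfinite(a)
    return tuple(a[ok] for a in arrs)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties and a
    t-approximation p-value; incomplete pairs are dropped."""
    xc, yc = _complete(np.asarray(x), np.asarray(y))
    n = len(xc)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        return CorrelationResult(float("nan"), float("nan"), n)
    rho, p = stats.spearmanr(xc, yc)
    return CorrelationResult(float(rho), float(p), n)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: np.ndarray | pd.DataFrame | None = None,
    control_names: Sequence[str] | None = None,
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given control columns.

    All columns are rank-transformed (average ranks); the partial
    correlation is read off the precision matrix Omega of the rank
    correlation matrix as ``-Omega_xy / sqrt(Omega_xx Omega_yy)``.  With no
    controls this equals :func:`spearman`.  Complete cases only.
    """
    if controls is None or (hasattr(controls, "shape") and controls.shape[-1] == 0) or (
        isinstance(controls, pd.DataFrame) and controls.shape[1] == 0
    ):
        res = spearman(x, y)
        return CorrelationResult(
            res.rho, res.p_value, res.n_windows, (), "partial"
        )
    if isinstance(controls, pd.DataFrame):
        names = tuple(map(str, controls.columns))
        cmat = controls.to_numpy(dtype=float)
    else:
        cmat = np.atleast_2d(np.asarray(controls, dtype=float))
        if cmat.shape[0] != len(np.asarray(x)):  # accept (k, n) layout too
            cmat = cmat.T
        names = (
            tuple(control_names)
            if control_names is not None
            else tuple(f"z{i}" for i in range(cmat.shape[1]))
        )
    cols = _complete(np.asarray(x), np.asarray(y), *cmat.T)
    n = len(cols[0])
    k = len(cols) - 2
    if n < 3 + k:
        raise ValueError("need at least 3 + #controls complete cases")
    ranks = np.column_stack([stats.rankdata(c) for c in cols])
    corr = np.corrcoef(ranks, rowvar=False)
    try:
        omega = np.linalg.inv(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"singular rank-correlation matrix; collinear controls among "
            f"{names}"
        ) from err
    if np.linalg.cond(corr) > 1e12:
        raise ValueError(
            f"near-singular rank-correlation matrix; collinear controls "
            f"among {names}"
        )
    rho = float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))
    rho = float(np.clip(rho, -1.0, 1.0))
    # t-approximation with k controls removed from the dof.
    dof = n - 2 - k
    if abs(rho) >= 1.0 or dof <= 0:
        p = 0.0 if abs(rho) >= 1.0 else float("nan")
    else:
        t = rho * np.sqrt(dof / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return CorrelationResult(rho, p, n, names, "partial")


def genic_permutation_test(
    windows: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    group_col: str = "window_class",
    groups: tuple[str, str] = ("genic", "nongenic"),
    n_perm: int = 10_000,
    sided: str = "greater",
    seed: int = 0,
    add_one: bool = True,
) -> PermutationTestResult:
    """Test whether a correlation statistic is larger in genic than
    non-genic windows.

    ``statistic`` maps a window subset (DataFrame) to a scalar (e.g. a
    Spearman rho against recombination rate).  The observed difference
    statistic(genic) - statistic(nongenic) is compared with the null
    distribution obtained by randomly reassigning windows to the two
    groups with group sizes fixed.

    Returns both the add-one p-value ``(#{diff_perm >= diff_obs}+1)/(n+1)``
    and the raw proportion.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if sided != "greater":
        raise ValueError("only the one-sided 'greater' test is provided")
    g1 = windows[windows[group_col] == groups[0]]
    g2 = windows[windows[group_col] == groups[1]]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 10:
        warnings.warn(
            "group size < 10: rank statistics are unstable", stacklevel=2
        )
    observed = statistic(g1) - statistic(g2)
    pool = pd.concat([g1, g2], ignore_index=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        d = statistic(pool.iloc[perm[:n1]]) - statistic(pool.iloc[perm[n1:]])
        if d >= observed:
            count += 1
    return PermutationTestResult(
        observed_diff=float(observed),
        n_perm=n_perm,
        p_value=(count + 1) / (n_perm + 1) if add_one else count / n_perm,
        p_value_proportion=count / n_perm,
        seed=seed,
    )


def bootstrap_ci(
    windows: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval over windows.

    Windows are resampled with replacement; a resample on which the
    statistic is undefined (nan) is redrawn (the redraw count is capped to
    keep termination guaranteed).
    """
    if len(windows) < 30:
        raise ValueError("need at least 30 windows to bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n = len(windows)
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            v = statistic(windows.iloc[idx])
            if np.isfinite(v):
                break
            redraws += 1
        vals[b] = v
    if redraws:
        warnings.warn(f"redrew {redraws} degenerate resamples", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def subset_by_percentile(
    windows: pd.DataFrame, column: str, percentile: float = 0.90
) -> pd.DataFrame:
    """Windows whose ``column`` value reaches the empirical percentile
    (e.g. 0.90 keeps the top decile of d_N)."""
    if not (0 <= percentile <= 1):
        raise ValueError("percentile must lie in [0, 1]")
    vals = windows[column].to_numpy(dtype=float)
    if percentile == 0:
        return windows.copy()
    cut = np.nanquantile(vals, percentile)
    return windows[vals >= cut].copy()


def bin_windows(
    windows: pd.DataFrame,
    sort_key: str = "recomb_rate",
    bin_size: int = 50,
    tie_break: Sequence[str] = ("chrom", "start"),
) -> pd.DataFrame:
    """Sort windows by ``sort_key`` and average consecutive groups of
    ``bin_size`` (for display as in the binned scatter figures).

    A trailing partial bin is retained and flagged in the ``partial``
    column.  Ties in the sort key are broken by genomic coordinate for
    reproducibility.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    by = [sort_key] + [c for c in tie_break if c in windows.columns]
    ordered = windows.sort_values(by, kind="stable").reset_index(drop=True)
    ordered["_bin"] = np.arange(len(ordered)) // bin_size
    numeric = ordered.select_dtypes(include=[np.number]).columns
    agg = ordered.groupby("_bin")[list(numeric)].mean()
    sizes = ordered.groupby("_bin").size()
    agg["n_windows"] = sizes
    agg["partial"] = sizes < bin_size
    return agg.drop(columns=["_bin"], errors="ignore").reset_index(drop=True)
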