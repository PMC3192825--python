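"""Forward-in-time Wright-Fisher simulation of 100 kb genomic windows.

Each simulated window carries 8 exons and 7 introns flanking a central
53 kb neutral intergenic block.  Mutations arise under an infinite-sites
Jukes-Cantor model at 2.5e-8 per bp per generation; nonsynonymous targets
are the first and second positions of exonic codons, third positions and
intergenic bases are neutral, and intronic mutations may be deleterious
with a configurable probability.  Recombination follows a hotspot map in
which 2 kb hotspots, spaced Exp(mean 20 kb) apart, carry 80% of the
window's genetic map with Dirichlet-distributed intensities, and the
background carries the remaining 20%.

Demography: an ancestral population (20,000 diploids) splits 200,000
generations ago into human and chimp populations of 10,000 each (a 2-fold
contraction), with an optional out-of-Africa-style bottleneck on the human
branch.  All parameters are rescaled by a factor ``lam`` (population sizes
and times divided, mutation/recombination/selection multiplied) so
population-scaled quantities are preserved; the burn-in can start from a
neutral-coalescent state (msprime) instead of a monomorphic population to
avoid paying the full equilibration time forward in time.

Measurement mirrors the data pipeline: only intergenic variation is
summarized, human-chimp divergence compares one human with one chimp
individual counting heterozygous sites as half a difference, and simulated
d_N is the fraction of human-chimp differences at first and second codon
positions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .correlation_suite import spearman
from .window_summaries import WindowSummary, tajimas_d

__all__ = [
    "INTERGENIC",
    "INTRON",
    "NONSYN",
    "SYN",
    "WindowLayout",
    "DemographicModel",
    "SelectionModel",
    "HotspotMap",
    "SimReplicate",
    "build_layout",
    "load_config",
    "sample_hotspot_map",
    "assign_recombination_rates",
    "expand_plan",
    "run_replicate",
    "run_equilibrium",
    "measure_replicate",
    "sweep_fixation_fraction",
    "simulation_study",
]

# site class codes
INTERGENIC, INTRON, NONSYN, SYN = 0, 1, 2, 3

MU_DEFAULT = 2.5e-8  # per bp per generation, Jukes-Cantor


# ---------------------------------------------------------------------------
# Window layout


@dataclass(frozen=True)
class WindowLayout:
    """Exon/intron/intergenic structure of a simulated window.

    ``features`` are ``(start, end, kind)`` half-open intervals in order;
    ``site_class`` maps every bp to INTERGENIC/INTRON/NONSYN/SYN, with
    exonic codon positions 1-2 as nonsynonymous targets and position 3 as
    synonymous (frame running left to right across all exons).
    """

    features: tuple[tuple[int, int, str], ...]
    site_class: np.ndarray

    @property
    def window_length(self) -> int:
        return int(self.site_class.size)

    @property
    def intergenic_positions(self) -> np.ndarray:
        return np.nonzero(self.site_class == INTERGENIC)[0]

    def class_count(self, code: int) -> int:
        return int((self.site_class == code).sum())

    @property
    def n_exons(self) -> int:
        return sum(1 for _, _, k in self.features if k == "exon")

    @property
    def n_introns(self) -> int:
        # the two half-introns adjoining the central block count as one
        full = sum(1 for _, _, k in self.features if k == "intron")
        halves = sum(1 for _, _, k in self.features if k == "half_intron")
        return full + halves // 2


def build_layout(
    exon_bp: int = 1500,
    intron_bp: int = 5000,
    intergenic_bp: int = 53_000,
    scale: float = 1.0,
    intergenic_scale: float | None = None,
    expected_length: int | None = None,
) -> WindowLayout:
    """Construct the default window: 4 exons and 3.5 introns on each side
    of a central neutral intergenic block (8 exons, 7 introns in total).

    With the defaults the window is 8 x 1.5 kb + 7 x 5 kb + 53 kb =
    100 kb.  ``scale`` shrinks every feature proportionally for reduced
    problem sizes; ``intergenic_scale`` (defaults to ``scale``) scales the
    central block separately, so reduced runs can keep the full selected
    architecture while shrinking only the neutral observation region.
    ``expected_length`` (if given) is checked against the realized total.
    """
    e = int(round(exon_bp * scale))
    i = int(round(intron_bp * scale))
    ih = i // 2
    ih2 = i - ih  # keep 2 half-introns summing to one intron exactly
    g_scale = scale if intergenic_scale is None else intergenic_scale
    c = int(round(intergenic_bp * g_scale))
    if min(e, ih, c) <= 0:
        raise ValueError("layout feature lengths must be positive")
    left = [
        ("exon", e), ("intron", i), ("exon", e), ("intron", i),
        ("exon", e), ("intron", i), ("exon", e), ("half_intron", ih),
    ]
    right = [
        ("half_intron", ih2), ("exon", e), ("intron", i), ("exon", e),
        ("intron", i), ("exon", e), ("intron", i), ("exon", e),
    ]
    plan = left + [("intergenic", c)] + right
    total = sum(n for _, n in plan)
    if expected_length is not None and total != expected_length:
        raise ValueError(
            f"layout totals {total} bp but {expected_length} was required"
        )
    features = []
    pos = 0
    site_class = np.empty(total, dtype=np.int8)
    coding_index = 0
    for kind, length in plan:
        start, end = pos, pos + length
        features.append((start, end, kind))
        if kind == "exon":
            for p in range(start, end):
                site_class[p] = SYN if coding_index % 3 == 2 else NONSYN
                coding_index += 1
        elif kind in ("intron", "half_intron"):
            site_class[start:end] = INTRON
        else:
            site_class[start:end] = INTERGENIC
        pos = end
    return WindowLayout(tuple(features), site_class)


# ---------------------------------------------------------------------------
# Hotspot maps


@dataclass
class HotspotMap:
    """Piecewise-constant recombination intensity for one window.

    Hotspots (fixed width) carry ``hotspot_mass`` of the window's total
    genetic length, split between them by a symmetric Dirichlet; the
    background segments share the remainder via an independent Dirichlet.
    ``spacings`` records the realized inter-hotspot distances (bp).
    """

    window_length: int
    hotspot_intervals: np.ndarray  # (k, 2) bp
    hotspot_weights: np.ndarray  # (k,), sums to 1 when k > 0
    background_intervals: np.ndarray  # (m, 2) bp
    background_weights: np.ndarray  # (m,), sums to 1
    hotspot_mass: float
    spacings: np.ndarray  # realized inter-hotspot gaps, bp

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All segments in bp order with their mass fractions.

        Returns ``(starts, ends, mass)`` where ``mass`` sums to 1.
        """
        k = len(self.hotspot_intervals)
        if k == 0:
            starts = self.background_intervals[:, 0].astype(float)
            ends = self.background_intervals[:, 1].astype(float)
            return starts, ends, self.background_weights.copy()
        segs = []
        for (s, e), w in zip(self.hotspot_intervals, self.hotspot_weights):
            segs.append((s, e, self.hotspot_mass * w))
        for (s, e), w in zip(self.background_intervals, self.background_weights):
            segs.append((s, e, (1.0 - self.hotspot_mass) * w))
        segs.sort()
        arr = np.array(segs, dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def realized_hotspot_mass(self) -> float:
        """Fraction of the map's genetic length inside hotspots."""
        if len(self.hotspot_intervals) == 0:
            return 0.0
        return float(self.hotspot_mass * self.hotspot_weights.sum())


def sample_hotspot_map(
    window_length: int,
    width: int = 2000,
    mean_spacing: float = 20_000.0,
    hotspot_mass: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> HotspotMap:
    """Sample a hotspot recombination map for one window.

    Hotspot starts are laid down left to right with gaps drawn from an
    exponential distribution with the given mean; a hotspot that would
    overrun the window is discarded and placement stops.  Hotspot
    intensities are ``hotspot_mass * x_i`` with ``x ~ Dirichlet(1, ..., 1)``
    over the k hotspots; background segments share ``1 - hotspot_mass``
    via an independent symmetric Dirichlet.  If no hotspot fits, all mass
    goes to the background.
    """
    if window_length <= width:
        raise ValueError("window must be longer than one hotspot")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hotspots: list[tuple[int, int]] = []
    gaps: list[float] = []
    x = 0.0
    while True:
        gap = rng.exponential(mean_spacing)
        start = x + gap
        if start + width > window_length:
            break
        if hotspots:
            gaps.append(start - hotspots[-1][1])
        hotspots.append((int(round(start)), int(round(start)) + width))
        x = start + width
    k = len(hotspots)
    hs = np.array(hotspots, dtype=np.int64).reshape(k, 2)
    hw = rng.dirichlet(np.ones(k)) if k > 0 else np.empty(0)
    # background = complement intervals with positive length
    bg = []
    prev = 0
    for s, e in hotspots:
        if s > prev:
            bg.append((prev, s))
        prev = e
    if window_length > prev:
        bg.append((prev, window_length))
    bgarr = np.array(bg, dtype=np.int64).reshape(len(bg), 2)
    bw = rng.dirichlet(np.ones(len(bg))) if len(bg) else np.empty(0)
    return HotspotMap(
        window_length=window_length,
        hotspot_intervals=hs,
        hotspot_weights=hw,
        background_intervals=bgarr,
        background_weights=bw,
        hotspot_mass=hotspot_mass if k > 0 else 0.0,
        spacings=np.array(gaps, dtype=float),
    )


class _CrossoverSampler:
    """Inverse-CDF sampler of crossover bp positions from a hotspot map."""

    def __init__(self, hmap: HotspotMap):
        starts, ends, mass = hmap.segments()
        keep = ends > starts
        self.starts = starts[keep]
        self.ends = ends[keep]
        m = mass[keep]
        total = m.sum()
        self.cum = np.concatenate([[0.0], np.cumsum(m / total)])
        self.cum[-1] = 1.0

    def sample_flat(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n crossover positions, unsorted (cum[0]=0 and u<1 bound j)."""
        u = rng.random(n)
        j = self.cum.searchsorted(u, side="right") - 1
        frac = (u - self.cum[j]) / np.maximum(self.cum[j + 1] - self.cum[j],
                                              1e-300)
        return self.starts[j] + frac * (self.ends[j] - self.starts[j])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.sort(self.sample_flat(n, rng))


# ---------------------------------------------------------------------------
# Demography and selection


@dataclass(frozen=True)
class DemographicModel:
    """Human/chimp split demography, unrescaled units (diploids, generations).

    The ancestral population of ``N_HC`` diploids splits ``t_split``
    generations before present into human and chimp populations of
    ``N_H``/``N_C`` (2-fold contractions of the ancestral size by default).
    An optional bottleneck shrinks the human branch to ``N_HBN`` between
    ``t_bn_start`` and ``t_bn_end`` generations before present.  Shipped
    bottleneck values are placeholders standing in for published European
    bottleneck fits and are fully configurable.
    """

    N_HC: int = 20_000
    N_H: int = 10_000
    N_C: int = 10_000
    t_split: int = 200_000
    N_HBN: int = 1_000
    t_bn_start: int = 1_500
    t_bn_end: int = 1_000
    bottleneck: bool = True

    def __post_init__(self) -> None:
        if min(self.N_HC, self.N_H, self.N_C, self.N_HBN) < 2:
            raise ValueError("population sizes must be at least 2 diploids")
        if not (self.t_split > self.t_bn_start > self.t_bn_end >= 0):
            raise ValueError("times must satisfy t_split > t_bn_start > "
                             "t_bn_end >= 0")

    def human_size_schedule(self, lam: float) -> np.ndarray:
        """Human branch diploid size for each rescaled generation after the
        split (index 0 = first post-split generation)."""
        t = max(int(round(self.t_split / lam)), 1)
        sizes = np.full(t, max(int(round(self.N_H / lam)), 2), dtype=np.int64)
        if self.bottleneck:
            bs = int(round(self.t_bn_start / lam))
            be = int(round(self.t_bn_end / lam))
            nb = max(int(round(self.N_HBN / lam)), 2)
            # generations-before-present g corresponds to index t-1-g
            for g in range(be, bs):
                idx = t - 1 - g
                if 0 <= idx < t:
                    sizes[idx] = nb
        return sizes

    def chimp_size_schedule(self, lam: float) -> np.ndarray:
        t = max(int(round(self.t_split / lam)), 1)
        return np.full(t, max(int(round(self.N_C / lam)), 2), dtype=np.int64)


@dataclass(frozen=True)
class SelectionModel:
    """Selection regime for one window class mixture.

    ``p_plus``/``p_minus`` are the fractions of windows containing positive
    and negative selection (the remainder are fully neutral).  In positive
    windows a fraction ``pos_fraction`` of nonsynonymous mutations get
    ``s = s_pos`` (the rest are neutral); in negative windows
    nonsynonymous selection coefficients are drawn from a (negated) gamma
    DFE and a fraction of intronic mutations carry ``-s_intron``.
    Selection coefficients are homozygote effects with dominance ``h``.
    The gamma defaults stand in for published human DFE fits and are
    configurable.
    """

    gamma_shape: float = 0.184
    gamma_mean: float = 0.03
    pos_fraction: float = 0.0
    s_pos: float = 0.00625
    intron_del_fraction: float = 0.0
    s_intron: float = 7.5e-5
    p_plus: float = 0.0
    p_minus: float = 0.0
    h: float = 0.5
    nonsyn_neutral_in_negative: bool = False  # True: skip the gamma DFE

    def __post_init__(self) -> None:
        for name in ("pos_fraction", "intron_del_fraction", "p_plus", "p_minus"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_plus + self.p_minus > 1 + 1e-12:
            raise ValueError("p_plus + p_minus must not exceed 1")

    def assign_window_type(self, rng: np.random.Generator) -> str:
        u = rng.random()
        if u < self.p_plus:
            return "positive"
        if u < self.p_plus + self.p_minus:
            return "negative"
        return "neutral"

    def draw_s(
        self,
        classes: np.ndarray,
        window_type: str,
        rng: np.random.Generator,
        lam: float = 1.0,
    ) -> np.ndarray:
        """Rescaled selection coefficients for new mutations by site class."""
        s = np.zeros(len(classes))
        if window_type == "neutral":
            return s
        nonsyn = classes == NONSYN
        if window_type == "positive":
            hit = nonsyn & (rng.random(len(classes)) < self.pos_fraction)
            s[hit] = self.s_pos * lam
        elif window_type == "negative":
            if not self.nonsyn_neutral_in_negative and nonsyn.any():
                scale = self.gamma_mean / self.gamma_shape
                draws = rng.gamma(self.gamma_shape, scale, size=int(nonsyn.sum()))
                s[nonsyn] = -draws * lam
            intron = classes == INTRON
            if intron.any() and self.intron_del_fraction > 0:
                hit = intron & (rng.random(len(classes)) < self.intron_del_fraction)
                s[hit] = -self.s_intron * lam
        return s


def load_config(path) -> dict:
    """Load a simulation configuration from YAML.

    Recognized top-level keys: ``layout`` (kwargs of :func:`build_layout`),
    ``demography`` (kwargs of :class:`DemographicModel`), ``selection``
    (kwargs of :class:`SelectionModel`), ``lam``, ``mu``, ``seed``,
    ``hotspots`` (kwargs of :func:`sample_hotspot_map`, minus the window
    length).  Returns a dict with instantiated objects plus scalars.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    layout = build_layout(**raw.get("layout", {}))
    return dict(
        layout=layout,
        demography=DemographicModel(**raw.get("demography", {})),
        selection=SelectionModel(**raw.get("selection", {})),
        lam=float(raw.get("lam", 40.0)),
        mu=float(raw.get("mu", MU_DEFAULT)),
        seed=int(raw.get("seed", 0)),
        hotspots=raw.get("hotspots", {}),
    )


def neutral_model() -> SelectionModel:
    return SelectionModel()


def background_selection_model(
    intron_del_fraction: float = 0.5, s_intron: float = 7.5e-5
) -> SelectionModel:
    """Gamma-DFE nonsynonymous selection plus weakly deleterious introns."""
    return SelectionModel(
        p_minus=1.0,
        intron_del_fraction=intron_del_fraction,
        s_intron=s_intron,
    )


def sweep_model(s_pos: float = 0.00625, pos_fraction: float = 0.005) -> SelectionModel:
    """Positive selection on a small fraction of nonsynonymous mutations,
    everything else neutral (all windows can sweep)."""
    return SelectionModel(p_plus=1.0, pos_fraction=pos_fraction, s_pos=s_pos)


def mixed_model(
    p_plus: float = 0.05,
    p_minus: float = 0.95,
    s_pos: float = 0.00625,
    pos_fraction: float = 0.005,
    intron_del_fraction: float = 0.5,
    s_intron: float = 7.5e-5,
) -> SelectionModel:
    """The headline mixture: a few sweep-capable windows amid widespread
    weak negative selection."""
    return SelectionModel(
        p_plus=p_plus,
        p_minus=p_minus,
        pos_fraction=pos_fraction,
        s_pos=s_pos,
        intron_del_fraction=intron_del_fraction,
        s_intron=s_intron,
    )


# ---------------------------------------------------------------------------
# Replicate plans


def assign_recombination_rates(
    empirical_rates: Sequence[float], n_bins: int = 100, n_total: int = 20_000
) -> pd.DataFrame:
    """Plan replicate counts per recombination-rate bin.

    Empirical per-window rates are split into ``n_bins`` equal-width bins;
    each occupied bin is represented by its midpoint rate, with replicate
    counts apportioned proportionally to bin occupancy (largest-remainder
    rounding so the total is exactly ``n_total``).
    """
    rates = np.asarray(empirical_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("recombination rates must be non-negative")
    if n_total == 0 or rates.size == 0:
        return pd.DataFrame(columns=["rate", "n_replicates"])
    lo, hi = rates.min(), rates.max()
    if hi == lo:
        return pd.DataFrame({"rate": [lo], "n_replicates": [n_total]})
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(rates, edges) - 1, 0, n_bins - 1)
    occ = np.bincount(which, minlength=n_bins)
    quota = occ / occ.sum() * n_total
    counts = np.floor(quota).astype(int)
    short = n_total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    mids = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    return pd.DataFrame({"rate": mids[keep], "n_replicates": counts[keep]})


def expand_plan(plan: pd.DataFrame) -> np.ndarray:
    """Flatten a replicate plan to one rate per replicate."""
    return np.repeat(plan["rate"].to_numpy(), plan["n_replicates"].to_numpy())


# ---------------------------------------------------------------------------
# Core engine


class _Population:
    """Haplotype pool for one panmictic population.

    ``H`` is a (2N, S) 0/1 int8 matrix over currently segregating
    mutations; parallel arrays hold positions, site classes, rescaled
    selection coefficients and mutation ids.  Fixed columns are removed
    and appended to ``fixed`` (id, position, class, s, generation index).
    """

    def __init__(self, H, pos, cls, s, ids, window_L: int | None = None):
        self.H = np.ascontiguousarray(H, dtype=np.int8)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.cls = np.asarray(cls, dtype=np.int8)
        self.s = np.asarray(s, dtype=float)
        self.ids = np.asarray(ids, dtype=np.int64)
        L = window_L if window_L is not None else (
            int(self.pos.max()) + 1 if len(self.pos) else 1
        )
        self.occupied = np.zeros(L, dtype=bool)
        self.occupied[self.pos] = True
        self.fixed: list[tuple[int, int, int, float, int]] = []
        self.n_generated = int(len(self.pos))
        self.n_lost = 0

    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def n_seg(self) -> int:
        return self.H.shape[1]

    def copy(self) -> "_Population":
        new = _Population(self.H.copy(), self.pos.copy(), self.cls.copy(),
                          self.s.copy(), self.ids.copy(),
                          window_L=len(self.occupied))
        return new

    def frequencies(self) -> np.ndarray:
        if self.n_seg == 0:
            return np.empty(0)
        return self.H.sum(axis=0, dtype=np.int64) / self.n_hap

    def check_conservation(self) -> bool:
        return self.n_generated == len(self.fixed) + self.n_lost + self.n_seg

    # -- one generation ----------------------------------------------------

    def _fitness(self, h_dom: float) -> np.ndarray:
        n_ind = self.n_hap // 2
        sel = np.nonzero(self.s != 0.0)[0]
        if sel.size == 0:
            return np.full(n_ind, 1.0)
        G = self.H[0::2][:, sel].astype(np.int16) + self.H[1::2][:, sel]
        s = self.s[sel]
        log_het = np.log(np.maximum(1.0 + h_dom * s, 1e-12))
        log_hom = np.log(np.maximum(1.0 + s, 1e-12))
        logw = (G == 1) @ log_het + (G == 2) @ log_hom
        return np.exp(logw - logw.max())

    def advance(
        self,
        n_child: int,
        G_morgans: float,
        mu_per_hap: float,
        window_L: int,
        site_class: np.ndarray,
        xover: _CrossoverSampler,
        draw_s,
        rng: np.random.Generator,
        h_dom: float = 0.5,
        gen_index: int = 0,
        cleanup: bool = True,
    ) -> "_Population":
        """Produce the next generation of ``n_child`` diploids."""
        S = self.n_seg
        n_gam = 2 * n_child
        n_parent = self.n_hap // 2
        if np.any(self.s != 0.0):
            w = self._fitness(h_dom)
            cum = np.cumsum(w)
            cum /= cum[-1]
            # u < 1 = cum[-1] bounds the index at n_parent - 1
            parents = cum.searchsorted(rng.random(n_gam), side="right")
        else:
            parents = rng.integers(0, n_parent, size=n_gam)
        coin = rng.integers(0, 2, size=n_gam)
        ncx = rng.poisson(G_morgans, size=n_gam) if G_morgans > 0 else np.zeros(
            n_gam, dtype=np.int64
        )
        n_mut = rng.poisson(n_gam * mu_per_hap)
        Hn = np.zeros((n_gam, S + n_mut), dtype=np.int8)
        if S:
            Hn[:, :S] = self.H[2 * parents + coin]
            cx_gam = np.nonzero(ncx > 0)[0]
            if cx_gam.size:
                counts_cx = ncx[cx_gam]
                flat = xover.sample_flat(int(counts_cx.sum()), rng)
                offs = np.concatenate([[0], np.cumsum(counts_cx)])
                for t, j in enumerate(cx_gam):
                    cx = np.sort(flat[offs[t] : offs[t + 1]])
                    hap = (coin[j] + cx.searchsorted(self.pos, side="right")) % 2
                    p = parents[j]
                    Hn[j, :S] = np.where(
                        hap == 0, self.H[2 * p], self.H[2 * p + 1]
                    )
        # new mutations: infinite sites on the integer lattice (collisions
        # with occupied positions or among the draws are redrawn)
        if len(self.occupied) < window_L:  # defensive: grow occupancy map
            grown = np.zeros(window_L, dtype=bool)
            grown[: len(self.occupied)] = self.occupied
            self.occupied = grown
        new_pos = np.empty(n_mut, dtype=np.int64)
        filled = 0
        while filled < n_mut:
            cand = np.unique(rng.integers(0, window_L, size=n_mut - filled))
            cand = cand[~self.occupied[cand]]
            self.occupied[cand] = True
            new_pos[filled : filled + len(cand)] = cand
            filled += len(cand)
        new_cls = site_class[new_pos] if n_mut else np.empty(0, dtype=np.int8)
        new_s = draw_s(new_cls, rng) if n_mut else np.empty(0)
        new_ids = _Population._next_ids(self, n_mut)
        if n_mut:
            rows = rng.integers(0, n_gam, size=n_mut)
            Hn[rows, S + np.arange(n_mut)] = 1
        child = _Population.__new__(_Population)
        child.H = Hn
        child.pos = np.concatenate([self.pos, new_pos])
        child.cls = np.concatenate([self.cls, new_cls]).astype(np.int8)
        child.s = np.concatenate([self.s, new_s])
        child.ids = np.concatenate([self.ids, new_ids])
        child.occupied = self.occupied  # shared ownership: parent discarded
        child.fixed = self.fixed
        child.n_generated = self.n_generated + n_mut
        child.n_lost = self.n_lost
        if cleanup:
            child._cleanup(gen_index)
        return child

    _id_counter = 0

    @staticmethod
    def _next_ids(pop: "_Population", n: int) -> np.ndarray:
        start = _Population._id_counter
        _Population._id_counter += n
        return np.arange(start, start + n, dtype=np.int64)

    def _cleanup(self, gen_index: int) -> None:
        if self.n_seg == 0:
            return
        counts = self.H.sum(axis=0, dtype=np.int64)
        lost = counts == 0
        fixed = counts == self.n_hap
        for j in np.nonzero(fixed)[0]:
            self.fixed.append(
                (int(self.ids[j]), int(self.pos[j]), int(self.cls[j]),
                 float(self.s[j]), gen_index)
            )
        drop = lost | fixed
        if drop.any():
            self.occupied[self.pos[drop]] = False
            self.n_lost += int(lost.sum())
            keep = ~drop
            self.H = np.ascontiguousarray(self.H[:, keep])
            self.pos = self.pos[keep]
            self.cls = self.cls[keep]
            self.s = self.s[keep]
            self.ids = self.ids[keep]


def _coalescent_init(
    n_dip: int,
    layout: WindowLayout,
    mu_r: float,
    rec_per_bp_r: float,
    selection: SelectionModel,
    window_type: str,
    rng: np.random.Generator,
) -> _Population:
    """Initialize a population at neutral-coalescent equilibrium.

    Only mutations that would be neutral under the selection model are
    planted (selected classes start empty and fill in during the
    selection burn-in); a uniform recombination rate equal to the map
    average is used for the initial genealogy.
    """
    import msprime

    L = layout.window_length
    ts = msprime.sim_ancestry(
        samples=n_dip,
        population_size=n_dip,
        sequence_length=L,
        recombination_rate=rec_per_bp_r,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu_r,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
    if len(pos) == 0:
        return _Population(
            np.zeros((2 * n_dip, 0), dtype=np.int8),
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8),
            np.empty(0), np.empty(0, dtype=np.int64), window_L=L,
        )
    Gm = mts.genotype_matrix()  # (sites, 2*n_dip)
    Gm = (Gm > 0).astype(np.int8)
    cls = layout.site_class[pos]
    # keep only classes that are neutral under this model
    keep = np.ones(len(pos), dtype=bool)
    keep &= cls != NONSYN  # nonsyn standing variation builds in burn-in
    if window_type == "negative" and selection.intron_del_fraction > 0:
        intron = cls == INTRON
        thin = rng.random(len(pos)) < selection.intron_del_fraction
        keep &= ~(intron & thin)
    if window_type == "positive":
        # nonsyn dropped above; 99.5% would be neutral, a conservative
        # simplification compensated by the selection burn-in
        pass
    pos, cls, Gm = pos[keep], cls[keep], Gm[keep]
    # de-duplicate positions (distinct sites share a bp only through edge
    # effects of the discrete genome)
    _, uniq = np.unique(pos, return_index=True)
    pos, cls, Gm = pos[uniq], cls[uniq], Gm[uniq]
    H = np.ascontiguousarray(Gm.T)
    s = np.zeros(len(pos))
    ids = _Population._next_ids(None, len(pos))  # type: ignore[arg-type]
    return _Population(H, pos, cls, s, ids, window_L=L)


@dataclass
class SimReplicate:
    """One simulated window: human sample, one chimp individual, and the
    mutation bookkeeping needed to measure diversity and divergence."""

    layout: WindowLayout
    hotspot_map: HotspotMap
    rate: float  # cM/Mb
    lam: float
    seed: int
    window_type: str
    # human branch
    human_pos: np.ndarray
    human_cls: np.ndarray
    human_ids: np.ndarray
    human_freq: np.ndarray  # derived frequency in the full human population
    human_sample: np.ndarray  # (2*n_sample, S_h) 0/1 haplotypes
    # chimp branch (one individual: 2 haplotypes)
    chimp_pos: np.ndarray
    chimp_cls: np.ndarray
    chimp_ids: np.ndarray
    chimp_ind: np.ndarray  # (2, S_c)
    fixations: pd.DataFrame  # branch, mutation_id, position, site_class, s, t
    counters: dict

    @property
    def n_sample(self) -> int:
        return self.human_sample.shape[0] // 2


def run_replicate(
    layout: WindowLayout,
    demography: DemographicModel,
    selection: SelectionModel,
    hotspot_map: HotspotMap | None,
    rate: float,
    mu: float = MU_DEFAULT,
    seed: int = 0,
    lam: float = 40.0,
    init: str = "coalescent",
    burn_in: int | None = None,
    n_sample: int = 6,
    window_type: str | None = None,
    cleanup_every: int = 4,
) -> SimReplicate:
    """Simulate one window forward in time through the split demography.

    Parameters
    ----------
    rate
        Sex-averaged recombination rate in cM/Mb (unrescaled).
    lam
        Rescaling factor: N and times divided by ``lam``; mutation,
        recombination and selection multiplied, so 4Nu, 4Nr and 2Ns are
        preserved.  ``lam = 40`` reproduces the reference run with an
        ancestral population of 500 diploids.
    init
        ``"coalescent"`` starts the ancestral burn-in from a neutral
        msprime equilibrium (selected classes empty) and defaults to a
        burn-in of 2 x 2N generations to equilibrate selection;
        ``"monomorphic"`` starts from zero variation and defaults to a
        burn-in of 10 x 2N generations.
    window_type
        Force ``"positive"``/``"negative"``/``"neutral"``; by default drawn
        from the selection model's p+/p- mixture.
    """
    rng = np.random.default_rng(seed)
    L = layout.window_length
    if hotspot_map is None:
        hotspot_map = sample_hotspot_map(L, seed=rng)
    mu_r = mu * lam
    rec_per_bp_r = rate * 1e-8 * lam  # Morgans per bp per generation
    G = rec_per_bp_r * L
    mu_per_hap = mu_r * L
    xover = _CrossoverSampler(hotspot_map)
    N_anc = max(int(round(demography.N_HC / lam)), 2)
    wtype = window_type or selection.assign_window_type(rng)

    def draw_s(classes, r):
        return selection.draw_s(classes, wtype, r, lam=lam)

    if init == "coalescent":
        pop = _coalescent_init(N_anc, layout, mu_r, rec_per_bp_r,
                               selection, wtype, rng)
        t_burn = burn_in if burn_in is not None else 2 * 2 * N_anc
    elif init == "monomorphic":
        pop = _Population(
            np.zeros((2 * N_anc, 0), dtype=np.int8),
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8),
            np.empty(0), np.empty(0, dtype=np.int64), window_L=L,
        )
        t_burn = burn_in if burn_in is not None else 10 * 2 * N_anc
    else:
        raise ValueError(f"unknown init mode {init!r}")

    common = dict(
        G_morgans=G, mu_per_hap=mu_per_hap, window_L=L,
        site_class=layout.site_class, xover=xover, draw_s=draw_s,
        h_dom=selection.h,
    )
    gen = 0
    for g in range(t_burn):
        gen += 1
        pop = pop.advance(N_anc, rng=rng, gen_index=gen,
                          cleanup=(g % cleanup_every == cleanup_every - 1),
                          **common)
    pop._cleanup(gen)
    anc_fixed = list(pop.fixed)
    anc_generated, anc_lost = pop.n_generated, pop.n_lost
    n_seg_split = pop.n_seg

    # split: human and chimp both sample their first generation from the
    # final ancestral parents
    human_sched = demography.human_size_schedule(lam)
    chimp_sched = demography.chimp_size_schedule(lam)
    t_branch = len(human_sched)
    chimp = pop.copy()
    chimp.fixed = []
    chimp.n_generated = n_seg_split
    chimp.n_lost = 0
    human = pop
    human.fixed = []
    human.n_generated = n_seg_split
    human.n_lost = 0
    for b, (branch, sched) in enumerate(
        (("human", human_sched), ("chimp", chimp_sched))
    ):
        p = human if branch == "human" else chimp
        for g in range(t_branch):
            p = p.advance(
                int(sched[g]), rng=rng, gen_index=g + 1,
                cleanup=(g % cleanup_every == cleanup_every - 1) or g == t_branch - 1,
                **common,
            )
        if branch == "human":
            human = p
        else:
            chimp = p

    # assemble records
    fix_rows = []
    for mid, posn, cl, s, g in anc_fixed:
        fix_rows.append(("ancestral", mid, posn, cl, s, float("nan")))
    for branch, p in (("human", human), ("chimp", chimp)):
        for mid, posn, cl, s, g in p.fixed:
            t_before = (t_branch - g) * lam
            fix_rows.append((branch, mid, posn, cl, s, t_before))
    fixations = pd.DataFrame(
        fix_rows,
        columns=["branch", "mutation_id", "position", "site_class", "s",
                 "t_before_present"],
    )
    samp = rng.choice(human.n_hap // 2, size=min(n_sample, human.n_hap // 2),
                      replace=False)
    rows = np.column_stack([2 * samp, 2 * samp + 1]).ravel()
    chimp_i = int(rng.integers(0, chimp.n_hap // 2))
    counters = dict(
        ancestral_generated=anc_generated,
        ancestral_lost=anc_lost,
        ancestral_fixed=len(anc_fixed),
        seg_at_split=n_seg_split,
        human_generated=human.n_generated,
        human_lost=human.n_lost,
        human_fixed=len(human.fixed),
        human_segregating=human.n_seg,
        chimp_generated=chimp.n_generated,
        chimp_lost=chimp.n_lost,
        chimp_fixed=len(chimp.fixed),
        chimp_segregating=chimp.n_seg,
    )
    return SimReplicate(
        layout=layout,
        hotspot_map=hotspot_map,
        rate=rate,
        lam=lam,
        seed=seed,
        window_type=wtype,
        human_pos=human.pos.copy(),
        human_cls=human.cls.copy(),
        human_ids=human.ids.copy(),
        human_freq=human.frequencies(),
        human_sample=human.H[rows].copy(),
        chimp_pos=chimp.pos.copy(),
        chimp_cls=chimp.cls.copy(),
        chimp_ids=chimp.ids.copy(),
        chimp_ind=chimp.H[[2 * chimp_i, 2 * chimp_i + 1]].copy(),
        fixations=fixations,
        counters=counters,
    )


def run_equilibrium(
    layout: WindowLayout,
    N: int,
    rate: float,
    mu: float = MU_DEFAULT,
    lam: float = 1.0,
    gens: int | None = None,
    selection: SelectionModel | None = None,
    window_type: str = "neutral",
    hotspot_map: HotspotMap | None = None,
    seed: int = 0,
    cleanup_every: int = 4,
) -> _Population:
    """Burn-in-only run of a single population (no split, no demography).

    Starts monomorphic and runs ``gens`` generations (default 10 x 2N
    rescaled) at constant rescaled size N/lam; used for stationarity
    calibration (diversity vs theta, site frequency spectrum).
    """
    rng = np.random.default_rng(seed)
    selection = selection or SelectionModel()
    L = layout.window_length
    if hotspot_map is None:
        hotspot_map = sample_hotspot_map(L, seed=rng)
    Nr = max(int(round(N / lam)), 2)
    gens = gens if gens is not None else 10 * 2 * Nr
    xover = _CrossoverSampler(hotspot_map)

    def draw_s(classes, r):
        return selection.draw_s(classes, window_type, r, lam=lam)

    pop = _Population(
        np.zeros((2 * Nr, 0), dtype=np.int8),
        np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8),
        np.empty(0), np.empty(0, dtype=np.int64), window_L=L,
    )
    for g in range(gens):
        pop = pop.advance(
            Nr, G_morgans=rate * 1e-8 * lam * L, mu_per_hap=mu * lam * L,
            window_L=L, site_class=layout.site_class, xover=xover,
            draw_s=draw_s, rng=rng, h_dom=selection.h, gen_index=g + 1,
            cleanup=(g % cleanup_every == cleanup_every - 1),
        )
    pop._cleanup(gens)
    return pop


# ---------------------------------------------------------------------------
# Measurement


def _half_rule(gh: int, gc: int) -> float:
    """Human-chimp difference contribution of one site from the two
    individuals' derived-allele dosages: 1 for opposite homozygotes, 0 for
    identical homozygotes, 0.5 whenever either individual is heterozygous.
    """
    if gh == gc:
        return 0.5 if gh == 1 else 0.0
    if {gh, gc} == {0, 2}:
        return 1.0
    return 0.5


def measure_replicate(
    rep: SimReplicate,
    coverage_law: np.ndarray | None = None,
    mode: str = "population-MAF",
    maf_threshold: float = 0.05,
    seed: int = 0,
) -> WindowSummary:
    """Summarize one replicate the way the data pipeline summarizes a
    window: intergenic-only diversity, single-individual divergence with
    the half-difference rule, and d_N from codon positions 1-2.

    Parameters
    ----------
    coverage_law
        Empirical distribution (array) of analyzed-intergenic-base counts;
        one value is drawn per replicate and a random subset of intergenic
        positions of that size is analyzed.  ``None`` analyses the full
        intergenic block.
    mode
        ``"population-MAF"`` calls SNPs from population frequencies with
        the folded-MAF threshold (low-coverage analogue);
        ``"sample-6"`` uses the sampled diploids' genotypes (genotype-data
        analogue; every segregating site in the sample is a SNP).
    """
    rng = np.random.default_rng(seed)
    lay = rep.layout
    inter = lay.intergenic_positions
    if coverage_law is not None:
        c = int(np.clip(rng.choice(np.asarray(coverage_law)), 1, len(inter)))
        analyzed = rng.choice(inter, size=c, replace=False)
    else:
        analyzed = inter
    analyzed_mask = np.zeros(lay.window_length, dtype=bool)
    analyzed_mask[analyzed] = True
    covered = int(analyzed_mask.sum())

    # --- diversity in the human branch
    h_inter = (rep.human_cls == INTERGENIC) & analyzed_mask[rep.human_pos]
    pi = float("nan")
    taj = float("nan")
    if mode == "population-MAF":
        folded = np.minimum(rep.human_freq, 1.0 - rep.human_freq)
        snp = h_inter & (folded > maf_threshold)
        S = int(snp.sum())
        mean_maf = float(folded[snp].mean()) if S else float("nan")
    elif mode == "sample-6":
        k = rep.human_sample.sum(axis=0, dtype=np.int64)
        n_hap = rep.human_sample.shape[0]
        seg = (k > 0) & (k < n_hap)
        snp = h_inter & seg
        S = int(snp.sum())
        kk = k[snp]
        folded = np.minimum(kk, n_hap - kk) / n_hap
        mean_maf = float(folded.mean()) if S else float("nan")
        if S:
            pi = float(np.sum(kk * (n_hap - kk)) / (n_hap * (n_hap - 1) / 2))
            taj = tajimas_d(S, pi, n_hap)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # --- divergence: one human individual vs one chimp individual
    gh_fix = {
        int(m): (int(p), int(c))
        for _, m, p, c in rep.fixations[rep.fixations.branch == "human"][
            ["mutation_id", "position", "site_class"]
        ].itertuples()
    }
    gc_fix = {
        int(m): (int(p), int(c))
        for _, m, p, c in rep.fixations[rep.fixations.branch == "chimp"][
            ["mutation_id", "position", "site_class"]
        ].itertuples()
    }
    human_ind = rep.human_sample[0] + rep.human_sample[1]
    chimp_ind = rep.chimp_ind[0] + rep.chimp_ind[1]
    site_g: dict[int, list] = {}
    for mid, (p, c) in gh_fix.items():
        site_g[mid] = [p, c, 2, 0]
    for mid, (p, c) in gc_fix.items():
        if mid in site_g:
            site_g[mid][3] = 2
        else:
            site_g[mid] = [p, c, 0, 2]
    for j, mid in enumerate(rep.human_ids):
        e = site_g.setdefault(
            int(mid), [int(rep.human_pos[j]), int(rep.human_cls[j]), 0, 0]
        )
        e[2] = int(human_ind[j])
    for j, mid in enumerate(rep.chimp_ids):
        e = site_g.setdefault(
            int(mid), [int(rep.chimp_pos[j]), int(rep.chimp_cls[j]), 0, 0]
        )
        e[3] = int(chimp_ind[j])
    d = 0.0
    d_nonsyn = 0.0
    for p, c, gh, gc in site_g.values():
        contrib = _half_rule(gh, gc)
        if contrib == 0.0:
            continue
        if c == INTERGENIC and analyzed_mask[p]:
            d += contrib
        elif c == NONSYN:
            d_nonsyn += contrib
    L_nonsyn = lay.class_count(NONSYN)
    d_N = d_nonsyn / L_nonsyn if L_nonsyn else float("nan")

    S_norm = (S / covered) / (d / covered) if (covered and d > 0) else float("nan")
    genic = (lay.class_count(NONSYN) + lay.class_count(SYN)
             + lay.class_count(INTRON)) / lay.window_length
    return WindowSummary(
        chrom="sim", start=0, end=lay.window_length,
        S=S, covered=covered, d=d, aligned=covered,
        S_norm=S_norm, mean_maf=mean_maf, pi=pi, tajimas_D=taj,
        genic_frac=genic, recomb_rate=rep.rate,
        d_N=d_N, valid=bool(covered and d > 0),
    )


def sweep_fixation_fraction(
    reps: Iterable[SimReplicate], horizon: float = 20_000.0
) -> float:
    """Fraction of windows with at least one positively selected
    nonsynonymous fixation on the human branch within ``horizon``
    (unrescaled) generations of the present."""
    n = 0
    hit = 0
    for rep in reps:
        n += 1
        f = rep.fixations
        sel = (
            (f.branch == "human")
            & (f.s > 0)
            & (f.site_class == NONSYN)
            & (f.t_before_present <= horizon)
        )
        if sel.any():
            hit += 1
    if n == 0:
        raise ValueError("no replicates supplied")
    return hit / n


def simulation_study(
    rates: Sequence[float],
    models: dict[str, SelectionModel],
    layout: WindowLayout | None = None,
    demography: DemographicModel | None = None,
    lam: float = 40.0,
    mode: str = "population-MAF",
    coverage_law: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
    **run_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run each selection model over the replicate plan and correlate the
    simulated summaries with recombination rate and d_N.

    Returns ``(summaries, correlations)``: per-replicate WindowSummary
    rows, and per-model Spearman rho with bootstrap CIs for
    (S_norm, rate), (mean_maf, rate), (S_norm, d_N) and (d, rate).
    """
    layout = layout or build_layout()
    demography = demography or DemographicModel()
    rng = np.random.default_rng(seed)
    rows = []
    for name, model in models.items():
        for r in rates:
            s = int(rng.integers(0, 2**31 - 1))
            rep = run_replicate(
                layout, demography, model, None, float(r),
                seed=s, lam=lam, **run_kwargs,
            )
            ws = measure_replicate(
                rep, coverage_law=coverage_law, mode=mode,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(
                dict(model=name, rate=float(r), S=ws.S, S_norm=ws.S_norm,
                     mean_maf=ws.mean_maf, d=ws.d, d_N=ws.d_N, pi=ws.pi,
                     window_type=rep.window_type)
            )
    summaries = pd.DataFrame(rows)
    pairs = [("S_norm", "rate"), ("mean_maf", "rate"),
             ("S_norm", "d_N"), ("d", "rate")]
    corr_rows = []
    for name in models:
        sub = summaries[summaries.model == name]
        for xcol, ycol in pairs:
            ok = np.isfinite(sub[xcol]) & np.isfinite(sub[ycol])
            x, y = sub[xcol][ok], sub[ycol][ok]
            if len(x) < 3 or x.nunique() < 2 or y.nunique() < 2:
                continue
            res = spearman(x, y)
            boots = np.empty(n_boot)
            brng = np.random.default_rng(
                [seed, abs(zlib.crc32(f"{name}:{xcol}:{ycol}".encode()))]
            )
            xv, yv = x.to_numpy(), y.to_numpy()
            for b in range(n_boot):
                idx = brng.integers(0, len(xv), size=len(xv))
                if len(np.unique(xv[idx])) < 2 or len(np.unique(yv[idx])) < 2:
                    boots[b] = np.nan
                    continue
                boots[b] = spearman(xv[idx], yv[idx]).rho
            lo, hi = np.nanquantile(boots, [0.025, 0.975])
            corr_rows.append(
                dict(model=name, x=xcol, y=ycol, rho=res.rho,
                     p_value=res.p_value, n=res.n_windows,
                     ci_low=float(lo), ci_high=float(hi))
            )
    return summaries, pd.DataFrame(corr_rows)
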