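"""Forward simulator: layout, hotspot maps, replicate plans, bookkeeping,
and the half-difference divergence rule."""

import numpy as np
import pandas as pd
import pytest

from linksel import wf_simulator as wf


class TestLayout:
    def test_default_window_structure(self):
        lay = wf.build_layout()
        assert lay.window_length == 100_000
        assert lay.n_exons == 8 and lay.n_introns == 7
        center = [f for f in lay.features if f[2] == "intergenic"]
        assert len(center) == 1
        s, e, _ = center[0]
        assert e - s == 53_000

    def test_codon_position_class_counts(self):
        lay = wf.build_layout()
        # 12 kb coding: 2/3 nonsynonymous targets, 1/3 synonymous
        assert lay.class_count(wf.NONSYN) == 8000
        assert lay.class_count(wf.SYN) == 4000
        assert lay.class_count(wf.INTRON) == 35_000
        assert lay.class_count(wf.INTERGENIC) == 53_000

    def test_scaled_layout_preserves_proportions(self):
        lay = wf.build_layout(scale=0.25)
        assert lay.window_length == 25_000
        assert lay.n_exons == 8

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValueError, match="required"):
            wf.build_layout(expected_length=90_000)


class TestHotspotMap:
    def test_weights_on_the_simplex(self):
        m = wf.sample_hotspot_map(100_000, seed=3)
        if len(m.hotspot_weights):
            assert m.hotspot_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.background_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_hotspots_all_background(self):
        # tiny window: a hotspot almost never fits
        m = wf.sample_hotspot_map(2_100, mean_spacing=1e9, seed=0)
        assert len(m.hotspot_intervals) == 0
        assert m.realized_hotspot_mass() == 0.0
        starts, ends, mass = m.segments()
        assert mass.sum() == pytest.approx(1.0)

    def test_segment_mass_partition(self):
        m = wf.sample_hotspot_map(200_000, seed=11)
        starts, ends, mass = m.segments()
        assert mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(starts[1:] >= ends[:-1] - 1e-9)  # ordered, disjoint

    def test_crossover_positions_inside_window(self):
        m = wf.sample_hotspot_map(100_000, seed=5)
        sampler = wf._CrossoverSampler(m)
        rng = np.random.default_rng(0)
        x = sampler.sample(1000, rng)
        assert x.min() >= 0 and x.max() <= 100_000
        assert np.all(np.diff(x) >= 0)

    def test_hotspots_receive_most_crossovers(self):
        m = wf.sample_hotspot_map(100_000, seed=21)
        assert len(m.hotspot_intervals) >= 1
        sampler = wf._CrossoverSampler(m)
        rng = np.random.default_rng(1)
        x = sampler.sample_flat(20_000, rng)
        in_hot = np.zeros(len(x), dtype=bool)
        for s, e in m.hotspot_intervals:
            in_hot |= (x >= s) & (x < e)
        assert abs(in_hot.mean() - 0.8) < 0.02


class TestReplicatePlan:
    def test_uniform_rates_equal_replicates(self):
        rates = np.linspace(0.005, 9.995, 10_000)
        plan = wf.assign_recombination_rates(rates, n_bins=100, n_total=20_000)
        assert plan["n_replicates"].sum() == 20_000
        assert (plan["n_replicates"] == 200).all()

    def test_identical_rates_single_bin(self):
        plan = wf.assign_recombination_rates([1.3] * 50, n_total=77)
        assert len(plan) == 1
        assert plan.iloc[0]["rate"] == 1.3
        assert plan.iloc[0]["n_replicates"] == 77

    def test_empty_plan(self):
        plan = wf.assign_recombination_rates([1.0, 2.0], n_total=0)
        assert len(plan) == 0

    def test_expand_matches_plan(self):
        plan = wf.assign_recombination_rates(
            np.random.default_rng(0).uniform(0, 3, 500), n_total=100
        )
        rates = wf.expand_plan(plan)
        assert len(rates) == 100


class TestConfigLoading:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "sim.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "layout": {"scale": 0.1},
                    "demography": {"bottleneck": False},
                    "selection": {"p_minus": 1.0, "intron_del_fraction": 0.5},
                    "lam": 100,
                }
            )
        )
        cfg = wf.load_config(path)
        assert cfg["layout"].window_length == 10_000
        assert cfg["demography"].bottleneck is False
        assert cfg["selection"].p_minus == 1.0
        assert cfg["lam"] == 100.0


class TestSelectionModel:
    def test_window_type_mixture(self):
        m = wf.mixed_model(p_plus=0.3, p_minus=0.5)
        rng = np.random.default_rng(0)
        types = [m.assign_window_type(rng) for _ in range(4000)]
        frac_pos = types.count("positive") / 4000
        frac_neg = types.count("negative") / 4000
        assert abs(frac_pos - 0.3) < 0.03 and abs(frac_neg - 0.5) < 0.03

    def test_neutral_window_all_zero(self):
        m = wf.mixed_model()
        rng = np.random.default_rng(1)
        s = m.draw_s(np.array([wf.NONSYN] * 100, dtype=np.int8), "neutral", rng)
        assert np.all(s == 0)

    def test_negative_window_classes(self):
        m = wf.background_selection_model()
        rng = np.random.default_rng(2)
        cls = np.array([wf.NONSYN] * 200 + [wf.INTRON] * 200
                       + [wf.SYN] * 50 + [wf.INTERGENIC] * 50, dtype=np.int8)
        s = m.draw_s(cls, "negative", rng, lam=10)
        assert np.all(s[cls == wf.NONSYN] < 0)
        intron_s = s[cls == wf.INTRON]
        frac_hit = (intron_s < 0).mean()
        assert 0.3 < frac_hit < 0.7  # 50% intronic targets
        assert np.allclose(intron_s[intron_s < 0], -7.5e-5 * 10)
        assert np.all(s[cls == wf.SYN] == 0)
        assert np.all(s[cls == wf.INTERGENIC] == 0)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            wf.SelectionModel(p_plus=0.6, p_minus=0.6)


class TestHalfDifferenceRule:
    @pytest.mark.parametrize(
        "gh,gc,expected",
        [
            (0, 2, 1.0),  # opposite homozygotes: one difference
            (2, 0, 1.0),
            (0, 0, 0.0),  # same homozygote: none
            (2, 2, 0.0),
            (1, 0, 0.5),  # any heterozygote: half a difference
            (0, 1, 0.5),
            (1, 2, 0.5),
            (1, 1, 0.5),
        ],
    )
    def test_cases(self, gh, gc, expected):
        assert wf._half_rule(gh, gc) == expected


class TestBookkeeping:
    def test_equilibrium_conservation_and_frequencies(self, small_equilibrium):
        pop = small_equilibrium
        assert pop.check_conservation()
        f = pop.frequencies()
        assert np.all((f > 0) & (f < 1))

    def test_replicate_counters_balance(self, small_replicate):
        c = small_replicate.counters
        assert c["human_generated"] == (
            c["human_fixed"] + c["human_lost"] + c["human_segregating"]
        )
        assert c["chimp_generated"] == (
            c["chimp_fixed"] + c["chimp_lost"] + c["chimp_segregating"]
        )
        assert c["ancestral_generated"] == (
            c["ancestral_fixed"] + c["ancestral_lost"] + c["seg_at_split"]
        )

    def test_replicate_deterministic_given_seed(self, small_replicate):
        rep2 = wf.run_replicate(
            small_replicate.layout,
            wf.DemographicModel(bottleneck=False),
            wf.neutral_model(),
            None,  # the map is drawn from the same seeded stream
            rate=1.0,
            seed=small_replicate.seed,
            lam=small_replicate.lam,
        )
        assert np.array_equal(rep2.human_pos, small_replicate.human_pos)
        assert np.array_equal(rep2.human_sample, small_replicate.human_sample)

    def test_deleterious_class_rarer_than_neutral(self):
        lay = wf.build_layout(scale=0.2)
        model = wf.SelectionModel(
            p_minus=1.0, intron_del_fraction=1.0, s_intron=2.5e-4,
            nonsyn_neutral_in_negative=True,
        )
        freqs_del, freqs_neu = [], []
        for seed in range(6):
            pop = wf.run_equilibrium(
                lay, N=8000, rate=1.0, lam=40, gens=1200,
                selection=model, window_type="negative", seed=seed,
            )
            f = pop.frequencies()
            freqs_del.extend(f[pop.s < 0])
            freqs_neu.extend(f[(pop.s == 0) & (pop.cls == wf.INTERGENIC)])
        assert np.mean(freqs_del) < np.mean(freqs_neu)


class TestSweepFixationCounting:
    def _rep_with_fixations(self, rows):
        fix = pd.DataFrame(
            rows,
            columns=["branch", "mutation_id", "position", "site_class", "s",
                     "t_before_present"],
        )
        rep = wf.SimReplicate.__new__(wf.SimReplicate)
        rep.fixations = fix
        return rep

    def test_no_positive_model_zero_fraction(self):
        reps = [self._rep_with_fixations(
            [("human", 1, 10, wf.NONSYN, -0.01, 100.0)]
        ) for _ in range(5)]
        assert wf.sweep_fixation_fraction(reps) == 0.0

    def test_horizon_and_class_filters(self):
        recent = self._rep_with_fixations(
            [("human", 1, 10, wf.NONSYN, 0.00625, 19_000.0)]
        )
        old = self._rep_with_fixations(
            [("human", 2, 10, wf.NONSYN, 0.00625, 21_000.0)]
        )
        chimp = self._rep_with_fixations(
            [("chimp", 3, 10, wf.NONSYN, 0.00625, 1_000.0)]
        )
        syn = self._rep_with_fixations(
            [("human", 4, 10, wf.SYN, 0.00625, 1_000.0)]
        )
        assert wf.sweep_fixation_fraction([recent, old, chimp, syn]) == 0.25

    def test_monotone_in_window_mixture(self):
        hit = self._rep_with_fixations(
            [("human", 1, 10, wf.NONSYN, 0.00625, 100.0)]
        )
        miss = self._rep_with_fixations([])
        # all-positive mixture dominates a 1-in-4 mixture
        all_pos = wf.sweep_fixation_fraction([hit] * 4)
        few_pos = wf.sweep_fixation_fraction([hit] + [miss] * 3)
        assert all_pos >= few_pos


class TestMeasurement:
    def test_summary_fields_sane(self, small_replicate):
        s = wf.measure_replicate(small_replicate, seed=1)
        assert s.covered == small_replicate.layout.class_count(wf.INTERGENIC)
        assert s.S >= 0 and s.d >= 0
        assert s.genic_frac == pytest.approx(
            1 - s.covered / small_replicate.layout.window_length
        )

    def test_coverage_law_subsets_intergenic(self, small_replicate):
        law = np.array([2000])
        s = wf.measure_replicate(small_replicate, coverage_law=law, seed=2)
        assert s.covered == 2000

    def test_sample_mode_computes_sfs_statistics(self, small_replicate):
        s = wf.measure_replicate(small_replicate, mode="sample-6", seed=3)
        if s.S > 1:
            assert np.isfinite(s.pi) and np.isfinite(s.tajimas_D)
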