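import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from v1phys import group_stats as gs
from v1phys._utils import round_sig
from v1phys.synthetic_data import SectionCountSimConfig, generate_pv_sections


class TestRoundSig:
    def test_two_sig_figs(self):
        assert round_sig(18.522, 2) == 19.0
        assert round_sig(0.01612, 2) == 0.016
        assert round_sig(227203, 2) == 230000
        assert round_sig(0.0, 2) == 0.0


class TestNormalityGate:
    def test_gate_level_on_normal_draws(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            hits += gs.normality_gate(x) == "normal"
        assert hits >= 90

    def test_power_on_lognormal(self):
        hits = 0
        for seed in range(50):
            x = np.exp(np.random.default_rng(seed).normal(0, 1.2, 26))
            hits += gs.normality_gate(x) == "non-normal"
        assert hits >= 40

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gs.normality_gate([1.0, 2.0])

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert gs.normality_gate(np.ones(10)) == "non-normal"


class TestCompareGroups:
    def test_identical_groups(self):
        x = np.arange(12, dtype=float)
        c = gs.compare_groups(x, x.copy())
        assert c.p_value > 0.9

    def test_summary_style_matches_gate(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = np.exp(rng.normal(0, 1.5, 30))
        c = gs.compare_groups(a, b)
        styles = {c.gate_a: c.summary_a["style"], c.gate_b: c.summary_b["style"]}
        for gate, style in styles.items():
            assert style == ("mean±SD" if gate == "normal" else "median+IQR")

    def test_shift_monotone_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        ps = []
        for shift in (0.0, 0.4, 0.8, 1.2, 1.6):
            res = stats.ttest_ind(a + shift, b, equal_var=False)
            ps.append(res.pvalue)
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_printed_effect_size_power(self):
        """Groups at the printed half-width means/SDs/ns reject far above the
        5% null level (empirical power of the printed effect ~ 40%)."""
        rng = np.random.default_rng(0)
        rej = 0
        for _ in range(200):
            a = rng.normal(0.9784, 0.1842, 25)
            b = rng.normal(0.8255, 0.2425, 11)
            rej += gs.compare_groups(a, b).p_value < 0.05
        assert rej / 200 > 0.25

    def test_signed_rank_requires_pairs(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(0, 2, 25))  # non-normal, so the rank branch is taken
        b = np.exp(rng.normal(0, 2, 26))
        with pytest.raises(ValueError, match="paired"):
            gs.compare_groups(a, b, rank_test="signed-rank")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gs.compare_groups([], [1.0, 2.0, 3.0])

    def test_type_I_error_level(self):
        """Null rejection rate of the gated comparison within [0.03, 0.07]."""
        rng = np.random.default_rng(7)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 12)
            rej += gs.compare_groups(a, b).p_value < 0.05
        assert 0.03 <= rej / n_rep <= 0.07


class TestBonferroni:
    def test_printed_table_value(self):
        assert gs.bonferroni([0.016], m=3)[0] == pytest.approx(0.048)

    def test_cap_at_one(self):
        assert gs.bonferroni([0.5], m=3)[0] == 1.0

    def test_zero_stays_zero(self):
        assert gs.bonferroni([0.0], m=10)[0] == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gs.bonferroni([1.5], m=3)
        with pytest.raises(ValueError):
            gs.bonferroni([0.1, 0.2, 0.3], m=2)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert gs.benjamini_hochberg([0.03])[0] == 0.03

    def test_hand_computed_example(self):
        out = gs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(gs.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert len(gs.benjamini_hochberg([])) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_bounded_by_raw_and_bonferroni(self, ps):
        out = gs.benjamini_hochberg(ps)
        bon = gs.bonferroni(ps)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        assert np.all(out <= bon + 1e-12)
        assert np.all(out <= 1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
    def test_matches_reference_implementation(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = gs.benjamini_hochberg(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)


class TestWilsonProportions:
    def test_equal_proportions_p_one(self):
        res = gs.wilson_proportions_test(20, 100, 20, 100, correction=False)
        assert res.p_value == pytest.approx(1.0)
        res_c = gs.wilson_proportions_test(20, 100, 20, 100, correction=True)
        assert res_c.p_value == pytest.approx(1.0)

    def test_strong_difference(self):
        res = gs.wilson_proportions_test(50, 100, 80, 100)
        assert res.p_value < 0.001

    def test_symmetry(self):
        a = gs.wilson_proportions_test(12, 40, 30, 50)
        b = gs.wilson_proportions_test(30, 50, 12, 40)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_r_prop_test(self):
        # frozen from R 4.3.3: prop.test(c(50,80), c(100,100)) -> X2 = 18.483516, p = 1.7138e-05
        res = gs.wilson_proportions_test(50, 100, 80, 100)
        assert res.statistic == pytest.approx(18.483516, abs=1e-5)
        assert res.p_value == pytest.approx(1.7138e-05, rel=1e-3)
        # prop.test(c(12,30), c(40,50)) -> X2 = 6.875558, p = 0.00873825
        res2 = gs.wilson_proportions_test(12, 40, 30, 50)
        assert res2.statistic == pytest.approx(6.875558, abs=1e-5)
        assert res2.p_value == pytest.approx(0.00873825, rel=1e-4)

    def test_wilson_intervals_cover_proportion(self):
        res = gs.wilson_proportions_test(30, 100, 50, 100)
        assert res.ci_1[0] < 0.3 < res.ci_1[1]
        assert res.ci_2[0] < 0.5 < res.ci_2[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gs.wilson_proportions_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            gs.wilson_proportions_test(11, 10, 1, 10)


class TestPvDensity:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        d = rng.normal(100, 5, 20)
        sec = pd.DataFrame(
            {
                "animal": ["WT1"] * 10 + ["TS1"] * 10,
                "genotype": ["WT"] * 10 + ["TS"] * 10,
                "area_mm2": 1.0,
                "count": np.concatenate([d[:10], d[:10]]).round().astype(int),
            }
        )
        res = gs.pv_density_analysis(sec)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.percent_difference == pytest.approx(0.0, abs=1e-10)

    def test_simulated_densities_recovered(self):
        cfg = SectionCountSimConfig(
            n_animals={"WT": 6, "TS": 6}, sections_per_animal=60, seed=0
        )
        sec = generate_pv_sections(cfg)
        res = gs.pv_density_analysis(sec)
        assert res.group_means["WT"] == pytest.approx(93.3, rel=0.03)
        assert res.group_means["TS"] == pytest.approx(114.9, rel=0.03)
        # configured ratio gives ~23% difference (the mean-of-sections estimator)
        assert res.percent_difference == pytest.approx(23.2, abs=3.0)
        assert res.p_value < 0.001

    def test_area_scaling_invariance(self):
        cfg = SectionCountSimConfig(seed=1)
        sec = generate_pv_sections(cfg)
        res1 = gs.pv_density_analysis(sec)
        sec2 = sec.copy()
        sec2["area_mm2"] *= 2.0
        sec2["count"] = sec2["count"] * 2  # density held fixed
        res2 = gs.pv_density_analysis(sec2)
        assert res2.percent_difference == pytest.approx(res1.percent_difference)
        assert res2.f_statistic == pytest.approx(res1.f_statistic)

    def test_zero_area_sections_dropped(self):
        sec = generate_pv_sections(SectionCountSimConfig(seed=2))
        sec.loc[0, "area_mm2"] = 0.0
        with pytest.warns(UserWarning, match="rejected"):
            res = gs.pv_density_analysis(sec)
        assert res.dropped_sections == 1

    def test_animal_level_advisory_present(self):
        sec = generate_pv_sections(SectionCountSimConfig(seed=3))
        res = gs.pv_density_analysis(sec)
        assert "p_value" in res.animal_level


class TestSectionSimulator:
    def test_density_equals_count_at_unit_area(self):
        cfg = SectionCountSimConfig(area_mean_mm2=1.0, area_sd_mm2=0.0, seed=0)
        sec = generate_pv_sections(cfg)
        assert np.allclose(sec["density"], sec["count"])

    def test_reproducible(self):
        a = generate_pv_sections(SectionCountSimConfig(seed=5))
        b = generate_pv_sections(SectionCountSimConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_overdispersion_increases_variance(self):
        tight = generate_pv_sections(
            SectionCountSimConfig(sections_per_animal=200, overdispersion=0.0, area_sd_mm2=0.0, seed=0)
        )
        wide = generate_pv_sections(
            SectionCountSimConfig(sections_per_animal=200, overdispersion=30.0, area_sd_mm2=0.0, seed=0)
        )
        v_t = tight.groupby("genotype")["count"].var()
        v_w = wide.groupby("genotype")["count"].var()
        assert (v_w > v_t).all()

    def test_min_sections_enforced(self):
        with pytest.raises(ValueError, match="eight"):
            SectionCountSimConfig(sections_per_animal=5)


class TestCorrectComparisons:
    def test_tiered_families(self):
        rng = np.random.default_rng(0)
        comps = []
        for i, tier in enumerate(["primary"] + ["secondary"] * 4):
            comps.append(
                gs.compare_groups(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                                  variable=f"v{i}", tier=tier)
            )
        gs.correct_comparisons(comps, primary_m=3)
        assert comps[0].correction == "bonferroni"
        assert comps[0].p_corrected == pytest.approx(min(1.0, comps[0].p_value * 3))
        secondary = comps[1:]
        ref = gs.benjamini_hochberg([c.p_value for c in secondary])
        for c, r in zip(secondary, ref):
            assert c.correction == "benjamini-hochberg"
            assert c.p_corrected == pytest.approx(r)
            assert c.p_corrected >= c.p_value
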