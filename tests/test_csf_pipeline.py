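import numpy as np
import pandas as pd
import pytest

from v1phys import csf_pipeline as csf


def flat_dataset(n_cells=2, n_frames=400, value=0.0, frame_rate=9.6):
    return csf.FluorescenceDataset(
        traces=np.full((n_cells, n_frames), value),
        frame_rate_hz=frame_rate,
        animal="A1",
        genotype="WT",
    )


def simple_epochs(n=4, ns=20, nb=20, sf=0.1, contrast=1.0):
    rows = []
    for p in range(n):
        onset = nb + p * (ns + nb)
        rows.append(
            {"onset_frame": onset, "offset_frame": onset + ns, "sf_cpd": sf,
             "contrast": contrast, "repeat": p}
        )
    return pd.DataFrame(rows)


class TestComputeDff:
    def test_constant_trace_zero(self):
        out = csf.compute_dff(np.full((1, 500), 100.0), 9.6, mode="raw")
        assert np.allclose(out, 0.0)

    def test_step_plateau(self):
        f = np.full(800, 100.0)
        f[400:] = 120.0
        out = csf.compute_dff(f[None, :], 9.6, mode="raw")
        # shortly after the step, before the rolling window catches up
        assert np.allclose(out[0, 420:500], 0.2, atol=1e-9)

    def test_dff_mode_passthrough(self):
        x = np.random.default_rng(0).normal(0, 1, (2, 100))
        assert np.array_equal(csf.compute_dff(x, 9.6, mode="dff"), x)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="cell rows"):
            csf.compute_dff(np.full((1, 500), -5.0), 9.6, mode="raw")

    def test_generator_amplitude_recovered(self, small_cohort):
        """Evoked dF/F close to the configured tuning amplitude."""
        cohort, truth = small_cohort
        _, ds, sched = next(cohort.items())
        tr = csf.trial_responses(ds, sched.epochs)
        # strongest stimulus of the strongest cell: compare with r_max
        top = tr.groupby(["cell", "sf_cpd", "contrast"])["evoked"].mean().max()
        r_max = cohort.config.tuning.r_max
        assert top == pytest.approx(r_max, rel=0.10)


class TestTrialResponses:
    def test_flat_trace_all_zero(self):
        tr = csf.trial_responses(flat_dataset(), simple_epochs())
        assert np.allclose(tr["evoked"], 0.0)

    def test_single_responsive_stimulus(self):
        ep = pd.concat(
            [simple_epochs(n=3, sf=0.014, contrast=1.0)], ignore_index=True
        )
        ds = flat_dataset(n_cells=1)
        tr = csf.trial_responses(ds, ep)
        assert len(tr) == 3

    def test_epoch_beyond_trace_rejected(self):
        ep = simple_epochs()
        ep.loc[len(ep) - 1, "offset_frame"] = 10_000
        with pytest.raises(ValueError, match="beyond trace length"):
            csf.trial_responses(flat_dataset(), ep)

    def test_baseline_mean_invariance(self):
        """Permuting frames inside a baseline window leaves responses unchanged."""
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 1, (3, 400))
        ds = csf.FluorescenceDataset(traces=traces, frame_rate_hz=9.6, animal="A", genotype="WT")
        ep = simple_epochs()
        t1 = csf.trial_responses(ds, ep)
        shuffled = traces.copy()
        b0, b1 = 40, 60  # the baseline preceding presentation 1
        shuffled[:, b0:b1] = shuffled[:, rng.permutation(np.arange(b0, b1))]
        ds2 = csf.FluorescenceDataset(traces=shuffled, frame_rate_hz=9.6, animal="A", genotype="WT")
        t2 = csf.trial_responses(ds2, ep)
        assert np.allclose(t1["evoked"], t2["evoked"])


class TestClassifyResponsive:
    def test_all_zero_nonresponsive(self):
        assert csf.classify_responsive(np.zeros(5)) is False

    def test_exact_permutation_positive_set(self):
        vals = np.array([0.5, 0.6, 0.4, 0.55, 0.5])
        assert csf.permutation_pvalue(vals) == pytest.approx(1 / 32)
        assert csf.classify_responsive(vals) is True

    def test_amplitude_floor_dominates(self):
        vals = np.array([0.04, 0.041, 0.039, 0.04, 0.04])
        assert csf.permutation_pvalue(vals) < 0.05
        assert csf.classify_responsive(vals) is False

    def test_too_few_repeats(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert csf.classify_responsive(np.array([0.5, 0.5])) is False


class TestMinResponsiveContrast:
    def test_monotone_pattern(self):
        assert csf.min_responsive_contrast({1.0: True, 0.5: True, 0.25: True, 0.125: False}) == 0.25
        assert np.log2(1 / 0.25) == 2.0

    def test_non_monotone_pattern_honoured(self):
        out = csf.min_responsive_contrast({1.0: True, 0.5: False, 0.25: False, 0.125: True})
        assert out == 0.125

    def test_none_responsive(self):
        assert csf.min_responsive_contrast({1.0: False, 0.5: False}) is None

    def test_max_category_value(self):
        assert np.log2(1 / 0.034) == pytest.approx(4.8783, abs=1e-3)


class TestCsTableAndPopulation:
    def test_category_anti_monotone_in_cmin(self, small_cohort):
        from conftest import cs_table_for

        cs = cs_table_for(small_cohort[0])
        ok = cs.dropna(subset=["contrast_sensitivity"])
        assert np.allclose(ok["contrast_sensitivity"], np.log2(1 / ok["min_responsive_contrast"]))
        assert (ok.loc[ok["min_responsive_contrast"] == 1.0, "contrast_sensitivity"] == 0).all()

    def test_nr_everywhere_never_visually_responsive(self, small_cohort):
        from conftest import cs_table_for

        cs = cs_table_for(small_cohort[0])
        all_nr = cs.groupby("cell")["contrast_sensitivity"].apply(lambda v: v.isna().all())
        flag = cs.groupby("cell")["visually_responsive"].first()
        assert not flag[all_nr].any()

    def test_population_identical_categories(self):
        tab = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(6)],
                "animal": "A1",
                "genotype": "WT",
                "sf_cpd": 0.1,
                "min_responsive_contrast": 0.25,
                "contrast_sensitivity": 2.0,
                "category": "2.0000",
                "visually_responsive": True,
            }
        )
        pop = csf.population_csf(tab)
        assert pop["mean_sensitivity"].iloc[0] == 2.0
        assert pop["q25"].iloc[0] == pop["q75"].iloc[0] == 2.0
        assert pop["fraction_nr"].iloc[0] == 0.0

    def test_population_known_distribution(self):
        """Analytic mean / linear-interpolated quartiles of {0,1,2,3}."""
        tab = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(4)],
                "animal": "A1",
                "genotype": "WT",
                "sf_cpd": 0.1,
                "min_responsive_contrast": [1.0, 0.5, 0.25, 0.125],
                "contrast_sensitivity": [0.0, 1.0, 2.0, 3.0],
                "category": "x",
                "visually_responsive": True,
            }
        )
        pop = csf.population_csf(tab)
        assert pop["mean_sensitivity"].iloc[0] == 1.5
        assert pop["q25"].iloc[0] == 0.75
        assert pop["q75"].iloc[0] == 2.25

    def test_population_single_cell_degenerate(self):
        tab = pd.DataFrame(
            [{"cell": "c0", "animal": "A1", "genotype": "WT", "sf_cpd": 0.1,
              "min_responsive_contrast": 0.5, "contrast_sensitivity": 1.0,
              "category": "1.0000", "visually_responsive": True}]
        )
        pop = csf.population_csf(tab)
        assert pop["mean_sensitivity"].iloc[0] == 1.0
        assert pop["q25"].iloc[0] == pop["q75"].iloc[0] == 1.0

    def test_all_nr_stratum(self):
        tab = pd.DataFrame(
            [{"cell": "c0", "animal": "A1", "genotype": "WT", "sf_cpd": 0.1,
              "min_responsive_contrast": np.nan, "contrast_sensitivity": np.nan,
              "category": "NR", "visually_responsive": True}]
        )
        pop = csf.population_csf(tab)
        assert pop["fraction_nr"].iloc[0] == 1.0
        assert np.isnan(pop["mean_sensitivity"].iloc[0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            csf.population_csf(pd.DataFrame())


class TestProportionResponding:
    def _table(self):
        rows = []
        for i in range(10):
            for sf, sens in ((0.014, 2.0 if i < 8 else np.nan), (0.128, 1.0 if i < 3 else np.nan)):
                rows.append(
                    {"cell": f"c{i}", "animal": "A1", "genotype": "WT", "sf_cpd": sf,
                     "min_responsive_contrast": np.nan if np.isnan(sens) else 2.0**-sens,
                     "contrast_sensitivity": sens, "category": "x",
                     "visually_responsive": True}
                )
        return pd.DataFrame(rows)

    def test_fractions(self):
        tab = self._table()
        assert csf.proportion_responding(tab, 0.014, "WT") == 0.8
        assert csf.proportion_responding(tab, 0.128, "WT") == 0.3
        assert csf.proportion_responding(tab, 0.014) == 0.8

    def test_everyone_responds(self):
        tab = self._table()
        tab.loc[np.isclose(tab["sf_cpd"], 0.014), "contrast_sensitivity"] = 1.0
        assert csf.proportion_responding(tab, 0.014, "WT") == 1.0

    def test_nobody_responds(self):
        tab = self._table()
        tab.loc[np.isclose(tab["sf_cpd"], 0.128), "contrast_sensitivity"] = np.nan
        assert csf.proportion_responding(tab, 0.128, "WT") == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            csf.proportion_responding(self._table(), 0.014, "TS")


class TestOrdinalDatasetExport:
    def test_levels_and_nr_bottom(self, small_cohort, small_calcium_cfg):
        from conftest import cs_table_for

        cs = cs_table_for(small_cohort[0])
        data = csf.ordinal_dataset_from_cs_table(cs, contrast_grid=small_calcium_cfg.contrast_grid)
        K = len(small_calcium_cfg.contrast_grid) + 1
        assert data["category"].between(1, K).all()
        nr_cells = cs[cs["contrast_sensitivity"].isna() & cs["visually_responsive"]]
        if len(nr_cells):
            merged = data.merge(
                nr_cells[["cell", "sf_cpd"]].rename(columns={"sf_cpd": "sf"}), on=["cell", "sf"]
            )
            assert (merged["category"] == 1).all()

    def test_drop_nr_shifts(self, small_cohort, small_calcium_cfg):
        from conftest import cs_table_for

        cs = cs_table_for(small_cohort[0])
        data = csf.ordinal_dataset_from_cs_table(
            cs, contrast_grid=small_calcium_cfg.contrast_grid, drop_nr=True
        )
        assert data["category"].min() >= 1
        assert len(data) < len(csf.ordinal_dataset_from_cs_table(cs, contrast_grid=small_calcium_cfg.contrast_grid))

    def test_levels_ordered(self):
        levels = csf.sensitivity_levels((1.0, 0.5, 0.25, 0.125, 0.067, 0.034))
        assert levels[0] == "NR"
        assert levels[1:] == sorted(levels[1:])
        assert levels[1] == 0.0
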