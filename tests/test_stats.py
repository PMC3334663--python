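import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import osteoct as o
from osteoct import reference_tables as rt


def toy_dataset(cells, parameter="Tb.Sp", compartment="total"):
    """cells: {(week, limb): [values per animal]} -> LongitudinalDataset."""
    rows = []
    for (week, limb), vals in cells.items():
        for animal, v in enumerate(vals, start=1):
            rows.append({"animal": animal, "limb": limb, "week": week,
                         "compartment": compartment, "parameter": parameter,
                         "value": float(v)})
    return o.LongitudinalDataset(pd.DataFrame(rows))


class TestCheckNormality:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            o.check_normality(rng.standard_normal(12)) < 0.05
            for _ in range(200)
        )
        assert rejections <= 20  # >= 90% of samples pass

    def test_bimodal_sample_rejected(self):
        x = np.array([0.0] * 6 + [10.0] * 6) + np.arange(12) * 1e-6
        assert o.check_normality(x) < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            o.check_normality([5.0] * 12)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            o.check_normality([1.0, 2.0])


class TestRmAnova:
    @pytest.mark.parametrize("n,seed", [(3, 42), (12, 7)])
    def test_matches_statsmodels_anovarm(self, n, seed):
        """F and p for every effect agree with the independent
        mixed-design implementation in statsmodels."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(seed)
        data = rng.normal(100, 10, size=(n, 3, 2))
        weeks, limbs = (2, 6, 10), ("MIA", "control")
        cells = {(w, l): data[:, i, j]
                 for i, w in enumerate(weeks) for j, l in enumerate(limbs)}
        ds = toy_dataset(cells)
        res = o.rm_anova(ds, "Tb.Sp", "total")
        tbl = AnovaRM(ds.records, depvar="value", subject="animal",
                      within=["week", "limb"]).fit().anova_table
        assert res.f_time == pytest.approx(tbl.loc["week", "F Value"],
                                           abs=1e-6)
        assert res.f_group == pytest.approx(tbl.loc["limb", "F Value"],
                                            abs=1e-6)
        assert res.f_interaction == pytest.approx(
            tbl.loc["week:limb", "F Value"], abs=1e-6)
        assert res.p_interaction == pytest.approx(
            tbl.loc["week:limb", "Pr > F"], abs=1e-9)

    def test_identical_limbs_give_zero_group_effects(self):
        rng = np.random.default_rng(1)
        per_animal = rng.normal(100, 10, size=(6, 3))
        cells = {(w, l): per_animal[:, i]
                 for i, w in enumerate((2, 6, 10)) for l in ("MIA", "control")}
        res = o.rm_anova(toy_dataset(cells), "Tb.Sp", "total")
        assert res.f_group == pytest.approx(0.0, abs=1e-10)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-10)

    def test_incomplete_design_rejected(self):
        cells = {(2, "MIA"): [1, 2, 3], (2, "control"): [1, 2, 3],
                 (6, "MIA"): [1, 2, 3], (6, "control"): [1, 2]}
        with pytest.raises(ValueError, match="incomplete|missing"):
            toy_dataset(cells).matrix("Tb.Sp", "total")

    def test_pure_animal_effect_gives_f_near_one(self):
        """With only an additive animal effect, all effect F's average ~ 1."""
        rng = np.random.default_rng(7)
        fs = []
        for _ in range(100):
            animal = rng.normal(0, 5, size=(12, 1, 1))
            data = 100 + animal + rng.normal(0, 3, size=(12, 3, 2))
            cells = {(w, l): data[:, i, j]
                     for i, w in enumerate((2, 6, 10))
                     for j, l in enumerate(("MIA", "control"))}
            res = o.rm_anova(toy_dataset(cells), "Tb.Sp", "total")
            fs.append(res.f_interaction)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.3)


class TestPairedTests:
    def test_zero_differences(self):
        cells = {(2, "MIA"): [1.0, 2.0, 3.0], (2, "control"): [1.0, 2.0, 3.0],
                 (6, "MIA"): [4.0, 5.0, 6.0], (6, "control"): [4.0, 5.0, 6.0]}
        res = o.paired_tests(toy_dataset(cells), "Tb.Sp", "total", gate=False)
        assert all(r.t == 0.0 and r.p_raw == 1.0 for r in res)

    def test_closed_form_t_statistic(self):
        # differences 1..5: t = dbar / (s_d / sqrt(n)) = 3/(1.5811/2.2361)
        ctl = [10.0, 20.0, 30.0, 40.0, 50.0]
        mia = [c + d for c, d in zip(ctl, [1, 2, 3, 4, 5])]
        cells = {(2, "MIA"): mia, (2, "control"): ctl}
        res = o.paired_tests(toy_dataset(cells), "Tb.Sp", "total", gate=False)
        assert res[0].t == pytest.approx(4.2426, abs=1e-4)

    def test_gate_blocks_null_data(self):
        coh = o.simulate_cohort(rt.null_cohort_design(seed=123))
        ds = o.LongitudinalDataset(coh)
        a = o.rm_anova(ds, "Tb.Sp", "total")
        res = o.paired_tests(ds, "Tb.Sp", "total", gate=True)
        if a.p_group >= 0.05 and a.p_interaction >= 0.05:
            assert res == []
        else:
            assert len(res) == 3

    def test_single_pair_rejected(self):
        cells = {(2, "MIA"): [1.0], (2, "control"): [2.0]}
        with pytest.raises(ValueError, match="2 pairs"):
            o.paired_tests(toy_dataset(cells), "Tb.Sp", "total", gate=False)


class TestHolm:
    def test_worked_example(self):
        assert o.holm_adjust([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert o.holm_adjust([0.37]) == pytest.approx([0.37])

    def test_cap_at_one(self):
        assert o.holm_adjust([0.5, 0.5, 0.5]) == pytest.approx([1, 1, 1])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for m in (1, 2, 3, 4, 7):
            for _ in range(40):
                p = np.round(rng.integers(0, 101, size=m) / 100, 2)
                assert np.allclose(o.holm_adjust(p),
                                   multipletests(p, method="holm")[1])

    def test_matches_closed_testing_definition(self):
        """Holm equals closed testing with Bonferroni local tests."""
        def closed_testing(p):
            m = len(p)
            out = []
            for i in range(m):
                worst = 0.0
                for r in range(1, m + 1):
                    for s in itertools.combinations(range(m), r):
                        if i in s:
                            worst = max(worst,
                                        min(1.0, len(s) * min(p[j]
                                                              for j in s)))
                out.append(worst)
            return out

        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(size=4)
            assert np.allclose(o.holm_adjust(p), closed_testing(list(p)))

    def test_dominance_sandwich(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=6)
            adj = o.holm_adjust(p)
            assert (adj >= p - 1e-12).all()
            assert (adj <= np.minimum(1, len(p) * p) + 1e-12).all()


class TestPercentDifference:
    @pytest.mark.parametrize("oa,ctl,expected", [
        (1260, 1456, -13.5),  # total BV at 2 weeks
        (271, 250, 8.4),      # total Tb.Sp at 2 weeks
        (647, 711, -9.0),     # lateral BV at 2 weeks
    ])
    def test_printed_style_values(self, oa, ctl, expected):
        assert round(o.percent_difference(oa, ctl), 1) == expected

    def test_identity_pair(self):
        assert o.percent_difference(3.7, 3.7) == 0.0

    def test_sign_antisymmetry_up_to_scale(self):
        # %d(a,b) = -%d(b,a) * a/b for positive pairs
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b = rng.uniform(1, 100, 2)
            assert o.percent_difference(a, b) == pytest.approx(
                -o.percent_difference(b, a) * a / b)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            o.percent_difference(1.0, 0.0)


class TestBuildTables:
    def test_large_cohort_recovers_design_means(self):
        design = rt.reference_cohort_design(parameters=["Tb.Sp"],
                                            n_animals=10_000, seed=3)
        ds = o.LongitudinalDataset(o.simulate_cohort(design))
        table = o.build_tables(ds, gate=False)
        merged = table.merge(
            design.effects[design.effects["limb"] == "MIA"],
            on=["parameter", "compartment", "week"])
        assert np.allclose(merged["mia_mean"], merged["mean"], rtol=0.01)

    def test_structure_per_parameter(self):
        coh = o.simulate_cohort(rt.null_cohort_design(seed=6))
        table = o.build_tables(o.LongitudinalDataset(coh), gate=False)
        assert len(table) == 3  # one row per timepoint
        assert set(table["parameter"]) == {"Tb.Sp"}
        assert "±" in table.loc[0, "mean_sd_mia"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            o.LongitudinalDataset(pd.DataFrame())


class TestOverTimeComparisons:
    def test_growth_trend_detected_within_control_limb(self):
        design = rt.reference_cohort_design(parameters=["Tb.Th"], seed=8)
        ds = o.LongitudinalDataset(o.simulate_cohort(design))
        res = o.paired_tests_over_time(ds, "Tb.Th", "total", "control")
        assert len(res) == 3  # (2,6), (2,10), (6,10)
        # control Tb.Th grows from 90 to 108 um across the study
        assert res[1].significant
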