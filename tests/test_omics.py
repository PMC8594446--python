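"""Differential-abundance statistics for omics tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edflux import omics, synth
from edflux.omics import OmicsTable


def _tiny_table(values, od=None, conditions=None, times=None, reps=None):
    values = pd.DataFrame(values)
    n = values.shape[1]
    values.columns = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "condition": conditions or ["a"] * n,
            "time_h": times or [0.0] * n,
            "replicate": reps or list(range(n)),
            "od600": od or [1.0] * n,
        },
        index=values.columns,
    )
    return OmicsTable(values, samples)


class TestNormalize:
    def test_od600_division(self):
        table = _tiny_table([[2.0, 4.0], [6.0, 8.0]], od=[0.5, 1.0])
        out = omics.normalize(table, mode="od600")
        np.testing.assert_allclose(out.values.to_numpy(), [[4.0, 4.0], [12.0, 8.0]])

    def test_doubling_od_halves_values(self):
        t1 = _tiny_table([[2.0, 4.0]], od=[0.5, 0.5])
        t2 = _tiny_table([[2.0, 4.0]], od=[1.0, 0.5])
        o1 = omics.normalize(t1, mode="od600")
        o2 = omics.normalize(t2, mode="od600")
        assert o2.values.iloc[0, 0] == o1.values.iloc[0, 0] / 2

    def test_unit_internal_standard_is_identity(self):
        table = _tiny_table([[2.0, 4.0], [6.0, 8.0]])
        std = pd.DataFrame(np.ones((2, 2)), index=table.values.index, columns=table.values.columns)
        out = omics.normalize(table, mode="internal_standard", standard=std)
        np.testing.assert_allclose(out.values.to_numpy(), table.values.to_numpy())

    def test_missing_od_rejected(self):
        table = _tiny_table([[1.0, 2.0]], od=[0.5, np.nan])
        with pytest.raises(ValueError, match="OD600"):
            omics.normalize(table, mode="od600")


class TestFoldChanges:
    def test_sample_equal_to_control_mean_is_zero(self):
        table = _tiny_table([[2.0, 2.0, 2.0, 2.0]], conditions=["c", "c", "c", "t"])
        fc = omics.fold_changes(table, ["s0", "s1", "s2"])
        t_row = fc[(fc["condition"] == "t")]
        assert t_row["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_threefold_change(self):
        table = _tiny_table([[2.0, 2.0, 2.0, 6.0]], conditions=["c", "c", "c", "t"])
        fc = omics.fold_changes(table, ["s0", "s1", "s2"])
        assert fc[fc["condition"] == "t"]["log2fc"].iloc[0] == pytest.approx(np.log2(3))

    def test_average_of_logs_not_log_of_average(self):
        # two replicates at 1x and 4x: avg of logs = 1, log of avg = log2(2.5)
        table = _tiny_table(
            [[2.0, 2.0, 8.0]], conditions=["c", "t", "t"], times=[0.0, 1.0, 1.0], reps=[0, 0, 1]
        )
        fc = omics.fold_changes(table, ["s0"])
        got = fc[fc["condition"] == "t"]["log2fc"].iloc[0]
        assert got == pytest.approx(1.0)
        assert got != pytest.approx(np.log2(2.5))

    def test_zero_control_mean_rejected(self):
        table = _tiny_table([[0.0, 1.0]], conditions=["c", "t"])
        with pytest.raises(ValueError):
            omics.fold_changes(table, ["s0"])


class TestFilterFeatures:
    def test_full_presence_kept_half_dropped(self):
        vals = pd.DataFrame(
            {
                "s0": [1.0, 1.0, np.nan],
                "s1": [1.0, np.nan, np.nan],
                "s2": [1.0, 1.0, np.nan],
                "s3": [1.0, np.nan, np.nan],
            },
            index=["full", "half", "empty"],
        )
        table = _tiny_table(vals.to_numpy())
        table.values.index = ["full", "half", "empty"]
        out = omics.filter_features(table)
        assert list(out.values.index) == ["full"]  # strict > 50%


class TestRMAnova:
    def test_hand_table_matches_textbook_partitioning(self):
        """3 subjects x 3 times; F and p frozen from the classical formulas."""
        y = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 5.0], [1.0, 4.0, 6.0]])
        F, p = omics.rm_anova_1way(y)
        assert F == pytest.approx(22.75, abs=1e-10)
        assert p == pytest.approx(0.00653, abs=5e-6)

    def test_matches_statsmodels_on_random_data(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(1)
        y = rng.normal(size=(4, 5))
        F, p = omics.rm_anova_1way(y)
        rows = [
            {"s": s, "t": t, "v": y[s, t]} for s in range(4) for t in range(5)
        ]
        res = AnovaRM(pd.DataFrame(rows), "v", "s", within=["t"]).fit()
        assert F == pytest.approx(float(res.anova_table["F Value"].iloc[0]), rel=1e-10)
        assert p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]), rel=1e-8)

    def test_constant_feature_gives_nan(self):
        F, p = omics.rm_anova_1way(np.ones((3, 4)))
        assert np.isnan(F) and np.isnan(p)

    def test_planted_three_sigma_time_effect_detected(self):
        """A 3-SD step over time is flagged at p<0.01 in >=95/100 runs."""
        rng = np.random.default_rng(11)
        sigma = 0.5
        shift = np.array([0.0, 3.0, 3.0, 3.0]) * sigma
        hits = 0
        for _ in range(100):
            y = shift[None, :] + rng.normal(0, sigma, size=(6, 4))
            _, p = omics.rm_anova_1way(y)
            hits += p < 0.01
        # analytic power for this design (noncentral F) is 0.98
        assert hits >= 95

    def test_incomplete_replicate_dropped(self):
        table = _tiny_table(
            [[1.0, 2.0, 1.5, 2.5, np.nan, 9.0]],
            conditions=["a"] * 6,
            times=[0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            reps=[0, 0, 1, 1, 2, 2],
        )
        p = omics.rm_anova_per_feature(table, "a")
        # replicate 2 (with the missing time-0 value) must not poison the test
        assert np.isfinite(p.iloc[0])


class TestMixedAnovaAndWelch:
    def test_mixed_anova_detects_condition_effect(self):
        rng = np.random.default_rng(2)
        cols, meta = {}, []
        for cond, shift in (("a", 0.0), ("b", 2.0)):
            for rep in range(4):
                for t in (0.0, 1.0):
                    name = f"{cond}{rep}t{t:g}"
                    cols[name] = [shift + rng.normal(0, 0.3)]
                    meta.append((name, cond, t, rep))
        values = pd.DataFrame(cols)
        samples = pd.DataFrame(
            [(c, t, r) for _, c, t, r in meta],
            index=[n for n, *_ in meta],
            columns=["condition", "time_h", "replicate"],
        )
        table = OmicsTable(values, samples)
        p = omics.mixed_anova_per_feature(table)
        assert p.iloc[0] < 0.01

    def test_mixed_anova_null_condition_not_flagged(self):
        rng = np.random.default_rng(4)
        cols, meta = {}, []
        for cond in ("a", "b"):
            for rep in range(4):
                for t in (0.0, 1.0):
                    name = f"{cond}{rep}t{t:g}"
                    cols[name] = [rng.normal(0, 0.3)]
                    meta.append((name, cond, t, rep))
        values = pd.DataFrame(cols)
        samples = pd.DataFrame(
            [(c, t, r) for _, c, t, r in meta],
            index=[n for n, *_ in meta],
            columns=["condition", "time_h", "replicate"],
        )
        p = omics.mixed_anova_per_feature(OmicsTable(values, samples))
        assert p.iloc[0] > 0.05

    def test_welch_matches_scipy_per_feature(self):
        import scipy.stats

        rng = np.random.default_rng(3)
        table, _ = synth.simulate_omics_tables(n_features=20, frac_de=0.2, seed=3)
        logt = omics.normalize(table, mode="od600", log2=True)
        p = omics.welch_t_per_feature(logt, "n2", "nh4")
        cols_a = logt.samples[logt.samples["condition"] == "n2"].index
        cols_b = logt.samples[logt.samples["condition"] == "nh4"].index
        for feat in list(logt.values.index[:5]):
            _, expected = scipy.stats.ttest_ind(
                logt.values.loc[feat, cols_a], logt.values.loc[feat, cols_b], equal_var=False
            )
            assert p[feat] == pytest.approx(float(expected), rel=1e-10)


class TestBHAndCalling:
    def test_hand_bh_case(self):
        adj = omics.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        adj = omics.bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw(self, ps):
        adj = omics.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            omics.bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize(
        "fc,fdr,expected",
        [
            (1.6, 0.04, True),
            (1.4, 0.01, False),
            (1.5, 0.05, True),  # inclusive boundary
            (0.5, 0.01, True),  # two-fold depletion
        ],
    )
    def test_significance_calls(self, fc, fdr, expected):
        assert bool(omics.call_significant(fc, fdr)) is expected

    def test_strict_mode_excludes_boundary(self):
        assert not omics.call_significant(1.5, 0.05, inclusive=False)


class TestORA:
    def test_term_equal_to_background_p_one(self):
        bg = {f"g{i}" for i in range(10)}
        out = omics.ora_hypergeom({"g0", "g1"}, bg, {"all": bg})
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_perfect_overlap_enumeration(self):
        from math import comb

        bg = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        out = omics.ora_hypergeom(term, bg, {"t": term})
        assert out.loc["t", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_p_decreases_with_overlap(self):
        bg = {f"g{i}" for i in range(40)}
        term = {f"g{i}" for i in range(10)}
        ps = []
        for k in (1, 3, 5):
            signif = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(20, 25)}
            out = omics.ora_hypergeom(signif, bg, {"t": term})
            ps.append(out.loc["t", "p"])
        assert ps[0] > ps[1] > ps[2]

    def test_empty_term_rejected(self):
        bg = {"a", "b"}
        with pytest.raises(ValueError):
            omics.ora_hypergeom({"a"}, bg, {"t": {"zzz"}})

    def test_signif_outside_background_rejected(self):
        with pytest.raises(ValueError):
            omics.ora_hypergeom({"x"}, {"a"}, {"t": {"a"}})
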