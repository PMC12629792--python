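"""Screens and survival statistics against enumeration/hand-worked oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.stats import hypergeom

from pdackit import InsufficientDataError, PdackitError
from pdackit import associations as assoc


def fisher_oracle(a, b, c, d):
    """Two-sided exact p by hypergeometric enumeration over the margins."""
    n = a + b + c + d
    row, col = a + b, a + c
    ks = np.arange(max(0, row + col - n), min(row, col) + 1)
    pmf = hypergeom.pmf(ks, n, row, col)
    obs = hypergeom.pmf(a, n, row, col)
    return float(pmf[pmf <= obs * (1 + 1e-12)].sum())


class TestFisherExact:
    def test_clearance_by_genotype_table(self):
        res = assoc.fisher_exact_test([[17, 3], [9, 9]])
        assert res["p_two_sided"] == pytest.approx(0.0354, abs=1e-4)

    def test_symmetric_table_p_one(self):
        assert assoc.fisher_exact_test([[5, 5], [5, 5]])["p_two_sided"] == 1.0

    def test_zero_margin(self):
        res = assoc.fisher_exact_test([[0, 0], [3, 4]])
        assert res["p_two_sided"] == 1.0
        assert np.isnan(res["odds_ratio"])

    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        res = assoc.fisher_exact_test([[a, b], [c, d]])
        assert res["p_two_sided"] == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


class TestBhAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert assoc.bh_adjust([0.42])[0] == 0.42

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_naive_step_up_oracle(self, ps):
        q = assoc.bh_adjust(ps)
        # naive step-up: q_(i) = min_{j>=i} m p_(j) / j, mapped back
        p = np.asarray(ps)
        order = np.argsort(p, kind="stable")
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        cummin = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(cummin, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    def test_monotone_and_order_invariant(self, ps):
        q = assoc.bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        shuffled = list(reversed(ps))
        q2 = assoc.bh_adjust(shuffled)
        np.testing.assert_allclose(list(reversed(q2)), q, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(PdackitError):
            assoc.bh_adjust([0.5, 1.5])


class TestFisherScreen:
    def test_rare_features_excluded(self, rng):
        features = pd.DataFrame(
            {"common": rng.random(20) < 0.5, "rare": [True, True] + [False] * 18}
        )
        endpoints = pd.DataFrame({"e": rng.random(20) < 0.5})
        out = assoc.fisher_screen(features, endpoints, min_altered=3)
        assert set(out["feature"]) == {"common"}

    def test_constant_endpoint_skipped(self, rng):
        features = pd.DataFrame({"f": rng.random(20) < 0.5})
        endpoints = pd.DataFrame({"e": [True] * 20})
        with pytest.warns(UserWarning):
            out = assoc.fisher_screen(features, endpoints)
        assert out.empty

    def test_perfect_feature_attains_margin_minimum(self):
        e = np.array([True] * 5 + [False] * 5)
        out = assoc.fisher_screen(pd.DataFrame({"f": e}), pd.DataFrame({"e": e}))
        assert out["p"].iloc[0] == pytest.approx(fisher_oracle(5, 0, 0, 5), abs=1e-12)

    def test_null_type_one_error_near_nominal(self, rng):
        # Fisher is conservative, so the rejection rate sits at or below ~5%
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            f = pd.DataFrame({"f": rng.random(100) < 0.5})
            e = pd.DataFrame({"e": rng.random(100) < 0.5})
            out = assoc.fisher_screen(f, e)
            hits += int(out["p"].iloc[0] < 0.05)
        rate = hits / n_rep
        assert 0.01 < rate <= 0.07


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        out = assoc.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        sf = out["survival_function"].set_index("time")["survival"]
        np.testing.assert_allclose(sf.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])
        assert out["median"] == 2

    def test_all_censored_median_undefined(self):
        out = assoc.km_estimate([5, 6, 7], [0, 0, 0])
        assert np.isnan(out["median"])
        assert (out["survival_function"]["survival"] == 1.0).all()

    def test_hand_worked_product_limit(self):
        # times 1(event) 2(censored) 3(event) 4(event):
        # S(1)=3/4, S(3)=3/4*1/2=3/8, S(4)=0
        out = assoc.km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        sf = out["survival_function"].set_index("time")["survival"]
        assert sf.loc[1] == pytest.approx(0.75)
        assert sf.loc[3] == pytest.approx(0.375)
        assert sf.loc[4] == pytest.approx(0.0)
        assert out["median"] == 3


def logrank_oracle_two_group(time, event, group, gehan=False):
    """Brute-force weighted O-E sums for the two-group test."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g0 = np.unique(group)[0]
    num = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at = time >= t
        n = at.sum()
        d = ((time == t) & (event == 1)).sum()
        n0 = (at & (group == g0)).sum()
        d0 = ((time == t) & (event == 1) & (group == g0)).sum()
        w = n if gehan else 1.0
        num += w * (d0 - d * n0 / n)
        if n > 1:
            var += w**2 * d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return num**2 / var


class TestWeightedLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [3, 5, 8, 11]
        out = assoc.weighted_logrank_test(t + t, [1, 1, 0, 1] * 2, ["a"] * 4 + ["b"] * 4)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_gehan_matches_brute_force(self, rng):
        t = rng.exponential(10, 40).round(1)
        e = (rng.random(40) < 0.8).astype(int)
        g = np.array(["a", "b"] * 20)
        out = assoc.weighted_logrank_test(t, e, g, weights="gehan")
        assert out["chi2"] == pytest.approx(logrank_oracle_two_group(t, e, g, gehan=True), abs=1e-9)

    def test_unit_weights_match_classic_logrank(self, rng):
        t = rng.exponential(10, 60).round(1)
        e = (rng.random(60) < 0.7).astype(int)
        g = np.array(["a", "b"] * 30)
        ours = assoc.weighted_logrank_test(t, e, g, weights="logrank")
        ref = logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert ours["chi2"] == pytest.approx(ref.test_statistic, abs=1e-12)
        assert ours["p"] == pytest.approx(ref.p_value, abs=1e-12)

    def test_gehan_more_sensitive_to_early_separation(self):
        # group a loses half its patients immediately, group b only late;
        # by the end both curves converge at 50% survival, so the early
        # difference is what a test must pick up
        ta = [1, 2, 3, 4, 5] + [100] * 5
        ea = [1] * 5 + [0] * 5
        tb = [50, 60, 70, 80, 90] + [100] * 5
        eb = [1] * 5 + [0] * 5
        t = np.array(ta + tb)
        e = np.array(ea + eb)
        g = np.array(["a"] * 10 + ["b"] * 10)
        gehan = assoc.weighted_logrank_test(t, e, g, weights="gehan")
        classic = assoc.weighted_logrank_test(t, e, g, weights="logrank")
        assert gehan["p"] < classic["p"]

    def test_single_group_rejected(self):
        with pytest.raises(PdackitError):
            assoc.weighted_logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def _sim(self, rng, n=300, log_hr=np.log(0.5)):
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(log_hr * x)))
        c = np.minimum(t, 400)
        return pd.DataFrame({"time": c, "event": (t <= 400).astype(int), "x": x})

    def test_identical_groups_hr_one(self):
        df = pd.DataFrame(
            {"time": [2, 4, 6, 8] * 2, "event": [1, 1, 1, 0] * 2, "x": [0] * 4 + [1] * 4}
        )
        out = assoc.cox_fit(df, "time", "event", "x")
        assert out["hr"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_rescaling_halves_log_hr(self, rng):
        df = self._sim(rng)
        out1 = assoc.cox_fit(df, "time", "event", "x")
        df2 = df.assign(x=df["x"] * 2)
        out2 = assoc.cox_fit(df2, "time", "event", "x")
        assert out2["coef"].iloc[0] == pytest.approx(out1["coef"].iloc[0] / 2, abs=1e-6)

    def test_matches_lifelines_breslow(self, rng):
        df = self._sim(rng)
        ours = assoc.cox_fit(df, "time", "event", "x")
        cph = CoxPHFitter().fit(df, "time", "event")
        assert ours["coef"].iloc[0] == pytest.approx(
            float(cph.params_.iloc[0]), abs=5e-3
        )  # lifelines uses Efron ties; agreement is close, not exact

    def test_interaction_and_categorical_terms(self, rng):
        df = self._sim(rng)
        df["geno"] = np.where(rng.random(len(df)) < 0.5, "G12V", "G12D")
        out = assoc.cox_fit(df, "time", "event", "x * C(geno, Treatment('G12V'))")
        assert len(out) == 3  # main effects + interaction
        assert out["ci_low"].le(out["hr"]).all() and out["hr"].le(out["ci_high"]).all()

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            assoc.cox_fit(df, "time", "event", "x")


class TestFoldChange:
    def _panel(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "day", "population", "frequency"])

    def test_doubling_and_unchanged(self):
        panel = self._panel(
            [("P1", "C1D1", "T", 5.0), ("P1", "C1D2", "T", 10.0),
             ("P2", "C1D1", "T", 4.0), ("P2", "C1D2", "T", 4.0)]
        )
        out = assoc.fold_change_table(panel, "C1D1", "C1D2").set_index("patient_id")
        assert out.loc["P1", "fold_change"] == 2.0
        assert out.loc["P2", "fold_change"] == 1.0

    def test_zero_baseline_and_missing_excluded(self):
        panel = self._panel(
            [("P1", "C1D1", "T", 0.0), ("P1", "C1D2", "T", 3.0), ("P2", "C1D2", "T", 3.0)]
        )
        out = assoc.fold_change_table(panel, "C1D1", "C1D2")
        assert out.empty

    def test_unknown_day_rejected(self):
        panel = self._panel([("P1", "C1D1", "T", 1.0)])
        with pytest.raises(PdackitError):
            assoc.fold_change_table(panel, "C1D1", "C9D9")


class TestNormalityGate:
    def test_normal_samples_take_t_branch(self, rng):
        out = assoc.normality_gated_compare(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
        assert out["test_used"] == "t-test"

    def test_skewed_samples_take_wilcoxon_branch(self, rng):
        out = assoc.normality_gated_compare(
            rng.lognormal(0, 2, 50), rng.lognormal(0, 2, 50)
        )
        assert out["test_used"] == "wilcoxon"

    def test_identical_groups_p_near_one(self, rng):
        x = rng.lognormal(0, 2, 30)
        out = assoc.normality_gated_compare(x, x.copy())
        assert out["p"] > 0.99

    def test_tiny_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            assoc.normality_gated_compare([1, 2], [1, 2, 3])


def best_sse_partition(X, k=2):
    """Exhaustive minimum-SSE assignment for small n."""
    n = len(X)
    best, best_sse = None, np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        labels = np.array(labels)
        sse = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum() for c in range(k)
        )
        if sse < best_sse - 1e-12:
            best, best_sse = labels, sse
    return best, best_sse


class TestKmeans:
    def test_separated_blobs_perfect_partition(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        labels = assoc.kmeans_cluster_samples(X, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_samples_co_cluster(self, rng):
        X = rng.normal(size=(6, 3))
        X2 = np.vstack([X, X])
        labels = assoc.kmeans_cluster_samples(X2, seed=0)
        np.testing.assert_array_equal(labels[:6], labels[6:])

    def test_small_n_matches_exhaustive_best_sse(self, rng):
        for _ in range(5):
            X = rng.normal(size=(7, 2))
            labels = assoc.kmeans_cluster_samples(X, seed=0)
            _, best_sse = best_sse_partition(X)
            sse = sum(
                ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
                for c in np.unique(labels)
            )
            assert sse == pytest.approx(best_sse, rel=1e-9)

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(PdackitError):
            assoc.kmeans_cluster_samples(rng.normal(size=(2, 2)), k=3)


class TestVariantFilter:
    def _variants(self):
        return pd.DataFrame(
            {
                "gene": ["KRAS", "TP53", "EGFR", "BRCA2", "BRCA1", "PALB2"],
                "maf_1000g": [0.0, 0.005, 0.02, 0.05, 0.002, np.nan],
                "maf_esp": [0.0, 0.004, 0.0, 0.04, 0.001, 0.03],
                "maf_gnomad": [0.001, 0.005, 0.0, 0.06, 0.003, 0.04],
                "impact": ["MODERATE", "MODERATE", "HIGH", "HIGH", "HIGH", "HIGH"],
            }
        )

    def test_somatic_rules(self):
        out = assoc.filter_somatic_variants(self._variants(), "somatic")
        genes = set(out["gene"])
        assert "EGFR" not in genes  # common in gnomAD -> germline-likely
        assert "KRAS" in genes and "TP53" in genes  # rare + moderate kept
        assert "BRCA2" not in genes

    def test_low_impact_removed(self):
        v = self._variants()
        v.loc[0, "impact"] = "LOW"
        out = assoc.filter_somatic_variants(v, "somatic")
        assert "KRAS" not in set(out["gene"])

    def test_ddr_germline_verbatim_direction(self):
        out = assoc.filter_somatic_variants(self._variants(), "ddr_germline")
        # published rule keeps COMMON high-impact DDR variants (MAF >= 0.01
        # in every observed population); rare BRCA1 is excluded by it
        assert set(out["gene"]) == {"BRCA2", "PALB2"}

    def test_ddr_germline_conventional_direction(self):
        out = assoc.filter_somatic_variants(
            self._variants(), "ddr_germline", strict_paper=False
        )
        assert set(out["gene"]) == {"BRCA1"}

    def test_missing_population_maf_kept_with_warning(self):
        with pytest.warns(UserWarning):
            out = assoc.filter_somatic_variants(self._variants(), "somatic")
        assert "PALB2" not in set(out["gene"])  # common in ESP/gnomAD regardless


class TestTmbMsi:
    def test_median_split_and_msi_rule(self):
        out = assoc.classify_tmb_msi([2.4, 5.0], [25.0, 10.0], tmb_median=2.65)
        assert out["tmb_class"].tolist() == ["low", "high"]
        assert out["msi_class"].tolist() == ["MSI", "MSS"]

    def test_tie_at_median_is_low(self):
        out = assoc.classify_tmb_msi([2.65], [0.0], tmb_median=2.65)
        assert out["tmb_class"].iloc[0] == "low"

    def test_cohort_median_recomputed(self):
        out = assoc.classify_tmb_msi([1.0, 2.0, 3.0, 10.0], [0, 0, 0, 0])
        assert out["tmb_median"].iloc[0] == 2.5
        assert out["tmb_class"].tolist() == ["low", "low", "high", "high"]


class TestConsensusKras:
    @pytest.mark.parametrize(
        "tissue,ctdna,expected",
        [
            ("G12V", "G12V", "G12V"),
            (None, "G12D", "G12D"),
            ("G12R", None, "G12R"),
            ("G12V", "G12D", "conflict"),
            (None, None, "undetermined"),
        ],
    )
    def test_rules(self, tissue, ctdna, expected):
        assert assoc.consensus_kras(tissue, ctdna) == expected


class TestConfoundingScreen:
    def test_duplicate_numeric_covariate_r_one(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x})
        out = assoc.confounding_screen(df, {"a": "numeric", "b": "numeric"})
        assert out["estimate"].iloc[0] == pytest.approx(1.0)

    def test_small_counts_route_to_fisher(self, rng):
        df = pd.DataFrame({"a": ["x"] * 4 + ["y"] * 4, "b": ["u", "v"] * 4})
        out = assoc.confounding_screen(df, {"a": "categorical", "b": "categorical"})
        assert out["test"].iloc[0] == "fisher"

    def test_large_counts_route_to_chi2(self, rng):
        df = pd.DataFrame(
            {"a": np.where(rng.random(200) < 0.5, "x", "y"),
             "b": np.where(rng.random(200) < 0.5, "u", "v")}
        )
        out = assoc.confounding_screen(df, {"a": "categorical", "b": "categorical"})
        assert out["test"].iloc[0] == "chi2"

    def test_cat_num_routes_to_anova(self, rng):
        df = pd.DataFrame({"a": ["x", "y"] * 15, "b": rng.normal(size=30)})
        out = assoc.confounding_screen(df, {"a": "categorical", "b": "numeric"})
        assert out["test"].iloc[0] == "anova"

    def test_single_level_covariate_skipped(self, rng):
        df = pd.DataFrame({"a": ["x"] * 10, "b": rng.normal(size=10)})
        out = assoc.confounding_screen(df, {"a": "categorical", "b": "numeric"})
        assert out.empty

    def test_q_values_attached(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40), "c": rng.normal(size=40)}
        )
        out = assoc.confounding_screen(df, {c: "numeric" for c in "abc"})
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()
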