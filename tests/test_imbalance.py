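import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from allelix.evaluation import call_cohort
from allelix.imbalance import (BetaBinomNull, CallThresholds, PoolingScheme,
                               betabinom_params, betabinom_pvalue,
                               betabinom_pvalues, call_imbalance,
                               fit_dispersion, pool_counts, sample_betabinom,
                               storey_pi0, storey_qvalues)
from allelix.synthetic_data import SimConfig, simulate_cohort


def brute_force_pvalue(k, n, rho):
    """Independent oracle: direct pmf summation of both tails."""
    ks = np.arange(n + 1)
    if rho == 0:
        pmf = stats.binom.pmf(ks, n, 0.5)
    else:
        a, b = betabinom_params(0.5, rho)
        pmf = stats.betabinom.pmf(ks, n, a, b)
    lower = pmf[: k + 1].sum()
    upper = pmf[k:].sum()
    return min(1.0, 2.0 * min(lower, upper))


class TestBetabinomPvalue:
    def test_center_is_one(self):
        assert betabinom_pvalue(10, 20, 0.05) == 1.0

    def test_extreme_binomial_closed_form(self):
        assert betabinom_pvalue(0, 10, 0.0) == pytest.approx(2 * 0.5**10, abs=1e-15)

    def test_symmetry(self):
        for k, n in [(2, 20), (7, 31), (0, 5)]:
            assert betabinom_pvalue(k, n, 0.1) == pytest.approx(
                betabinom_pvalue(n - k, n, 0.1), abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.01, 0.1, 0.3])
    def test_agrees_with_bruteforce_all_n_to_200(self, rho):
        rng = np.random.default_rng(0)
        ks, ns = [], []
        for n in range(1, 201):
            for k in {0, n // 4, n // 2, n, int(rng.integers(0, n + 1))}:
                ks.append(k)
                ns.append(n)
        ks, ns = np.array(ks), np.array(ns)
        got = betabinom_pvalues(ks, ns, rho)
        want = np.array([brute_force_pvalue(k, n, rho) for k, n in zip(ks, ns)])
        assert np.max(np.abs(got - want)) < 1e-10

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            betabinom_pvalue(1, 10, 1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            betabinom_pvalue(11, 10, 0.1)

    @given(n=st.integers(1, 150), frac=st.floats(0, 1),
           rho=st.floats(0, 0.4))
    @settings(max_examples=50, deadline=None)
    def test_pvalues_are_valid_probabilities(self, n, frac, rho):
        k = int(round(frac * n))
        p = betabinom_pvalue(k, n, rho)
        assert 0 < p <= 1


class TestFitDispersion:
    def _counts(self, rho, n_sites=5000, depth=200, seed=0):
        rng = np.random.default_rng(seed)
        n = np.full(n_sites, depth)
        k = sample_betabinom(rng, n, 0.5, rho)
        return k, n

    def test_binomial_data_recovers_near_zero(self):
        k, n = self._counts(0.0)
        fit = fit_dispersion(k, n, "c")
        assert fit.rho < 0.005

    def test_known_dispersion_recovered(self):
        k, n = self._counts(0.05)
        fit = fit_dispersion(k, n, "c")
        assert 0.04 <= fit.rho <= 0.06

    def test_too_few_deep_sites_errors(self):
        k, n = self._counts(0.05, n_sites=10)
        with pytest.raises(ValueError, match="pool conditions"):
            fit_dispersion(k, n, "c")

    def test_shallow_sites_do_not_inform_fit(self):
        k, n = self._counts(0.05)
        k2 = np.concatenate([k, np.zeros(1000, dtype=int)])
        n2 = np.concatenate([n, np.full(1000, 50)])  # extreme shallow sites
        fit = fit_dispersion(k2, n2, "c")
        assert fit.n_sites_used == len(k)
        assert 0.04 <= fit.rho <= 0.06


class TestStorey:
    def test_all_ones(self):
        q = storey_qvalues(np.ones(200))
        assert (q == 1.0).all()

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(1)
        p = rng.random(500) ** 2
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_uniform_pvalues_estimate_pi0_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.random(10_000)
        assert 0.9 <= storey_pi0(p) <= 1.0

    def test_mixture_pi0_detects_signal(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.random(8000), rng.beta(0.1, 10, 2000)])
        pi0 = storey_pi0(p)
        assert 0.7 <= pi0 <= 0.9

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


class TestPooling:
    def _scheme(self):
        return PoolingScheme.from_frame(pd.DataFrame({
            "sample_id": ["a1", "a2", "b1"],
            "cell_type": ["liver", "liver", "kidney"],
            "strain": ["s1", "s2", "s1"],
        }))

    def test_cell_type_pooling_sums(self):
        counts = pd.DataFrame({
            "snv_id": ["x", "x"], "condition_id": ["a1", "a2"],
            "ref_count": [10, 20], "nonref_count": [5, 5],
        })
        pooled = pool_counts(counts, self._scheme(), "cell_type")
        assert len(pooled) == 1
        assert pooled.loc[0, ["ref_count", "nonref_count"]].tolist() == [30, 10]

    def test_sample_level_is_identity(self):
        counts = pd.DataFrame({
            "snv_id": ["x", "y"], "condition_id": ["a1", "b1"],
            "ref_count": [1, 2], "nonref_count": [3, 4],
        })
        pooled = pool_counts(counts, self._scheme(), "sample")
        assert sorted(pooled["group_id"]) == ["a1", "b1"]
        assert pooled[["ref_count", "nonref_count"]].sum().sum() == 10

    def test_aggregate_conserves_totals(self):
        counts = pd.DataFrame({
            "snv_id": ["x", "x", "y"], "condition_id": ["a1", "a2", "b1"],
            "ref_count": [1, 2, 3], "nonref_count": [4, 5, 6],
        })
        pooled = pool_counts(counts, self._scheme(), "aggregate")
        assert pooled["ref_count"].sum() == 6
        assert pooled["nonref_count"].sum() == 15


class TestCallImbalance:
    def _null(self, rho=0.02):
        return {"all": BetaBinomNull("all", rho, 100, 0.0)}

    def test_below_min_reads_not_tested(self):
        pooled = pd.DataFrame({"snv_id": ["a", "b"], "group_id": ["all"] * 2,
                               "ref_count": [29, 30], "nonref_count": [0, 0]})
        calls = call_imbalance(pooled, self._null(), level="aggregate")
        assert list(calls["snv_id"]) == ["b"]

    def test_ratio_exactly_070_not_flagged(self):
        # strong significance but ratio exactly at the strict threshold
        pooled = pd.DataFrame({"snv_id": ["a"], "group_id": ["all"],
                               "ref_count": [700], "nonref_count": [300]})
        calls = call_imbalance(pooled, self._null(rho=0.0), level="aggregate")
        assert calls.loc[0, "q_value"] < 0.1
        assert not calls.loc[0, "imbalanced"]

    def test_missing_null_errors(self):
        pooled = pd.DataFrame({"snv_id": ["a"], "group_id": ["liver"],
                               "ref_count": [40], "nonref_count": [2]})
        with pytest.raises(ValueError, match="no fitted null"):
            call_imbalance(pooled, self._null(), level="cell_type")

    def test_null_cohort_flags_almost_nothing(self):
        cohort = simulate_cohort(SimConfig(seed=13, n_snvs=20_000,
                                           fraction_causal=0.0))
        calls = call_cohort(cohort)
        assert calls["imbalanced"].mean() <= 0.005

    def test_flag_invariant_holds(self, small_cohort):
        calls = call_cohort(small_cohort)
        flagged = calls[calls["imbalanced"]]
        major = np.maximum(flagged["allelic_ratio"], 1 - flagged["allelic_ratio"])
        assert (flagged["q_value"] <= 0.10).all()
        assert (major > 0.70).all()
        assert (flagged["total"] >= 30).all()


class TestStatisticalProperties:
    def test_fdr_controlled_on_cohorts_with_known_truth(self):
        # realized FDP among flagged calls across seeds stays at or below
        # the nominal 10% plus Monte-Carlo slack
        from allelix.evaluation import realized_fdr_percent

        fdp, fp, flagged = realized_fdr_percent(range(1, 6), n_snvs=20_000)
        se = 100 * np.sqrt(0.1 * 0.9 / max(flagged, 1))
        assert fdp <= 10.0 + 3 * se

    def test_power_monotone_in_depth_and_effect(self):
        rng = np.random.default_rng(7)
        rho = 0.03
        null = {"all": BetaBinomNull("all", rho, 100, 0.0)}
        th = CallThresholds()
        power = {}
        for depth in (40, 100, 300):
            for eff in (0.1, 0.2, 0.3):
                n = np.full(2000, depth)
                k = sample_betabinom(rng, n, 0.5 + eff, rho)
                pooled = pd.DataFrame({
                    "snv_id": [f"s{i}" for i in range(2000)],
                    "group_id": "all", "ref_count": k, "nonref_count": n - k})
                calls = call_imbalance(pooled, null, th, "aggregate")
                power[(depth, eff)] = calls["imbalanced"].mean()
        for eff in (0.1, 0.2, 0.3):
            assert power[(40, eff)] <= power[(100, eff)] + 0.02
            assert power[(100, eff)] <= power[(300, eff)] + 0.02
        for depth in (40, 100, 300):
            assert power[(depth, 0.1)] <= power[(depth, 0.2)] + 0.02
            assert power[(depth, 0.2)] <= power[(depth, 0.3)] + 0.02

    def test_null_ratio_histogram_symmetric(self):
        # no bias toward the reference allele: ref-higher and ref-lower
        # sites are equally frequent (sign test) and the mean sits at 0.5
        cohort = simulate_cohort(SimConfig(seed=17, n_snvs=15_000,
                                           fraction_causal=0.0))
        calls = call_cohort(cohort)
        r = calls["allelic_ratio"].to_numpy()
        above, below = int((r > 0.5).sum()), int((r < 0.5).sum())
        sign = stats.binomtest(above, above + below, 0.5)
        assert sign.pvalue > 0.01
        assert abs(r.mean() - 0.5) < 3 * r.std() / np.sqrt(len(r))
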