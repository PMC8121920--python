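import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

from allelix.cato2 import (Cato2ModelBundle, fit_combiner, fit_global_model,
                           fit_tf_model, precision_recall, score_variants,
                           standardize_annotations, train_bundle)
from allelix.evaluation import call_cohort
from allelix.motif_profiles import snv_motif_assignments
from allelix.synthetic_data import SimConfig, simulate_cohort


def _annotations(n, rng):
    return pd.DataFrame({
        "snv_id": [f"s{i}" for i in range(n)],
        "mcv": rng.random(n),
        "intron": rng.random(n) < 0.3,
        "intergenic": rng.random(n) < 0.3,
        "dist_tss": rng.integers(0, 100_000, n),
        "dhs_strength": rng.lognormal(0, 0.5, n),
        "dhs_width": rng.integers(150, 400, n),
        "footprint": rng.random(n) < 0.4,
        "nearby_sites": rng.poisson(2, n),
        "conservation": rng.random(n),
    })


class TestStandardize:
    def test_self_reference_scales_to_one(self):
        rng = np.random.default_rng(0)
        a = _annotations(500, rng)
        std_df, std = standardize_annotations(a, reference=a)
        assert all(np.isclose(v, 1.0) for v in std.scale.values())
        assert abs(std_df["mcv"].mean()) < 1e-9
        assert std_df["mcv"].std(ddof=0) == pytest.approx(1.0)

    def test_double_mean_gives_half_scale(self):
        rng = np.random.default_rng(1)
        a = _annotations(500, rng)
        b = a.copy()
        a2 = a.copy()
        a2["conservation"] = a["conservation"] * 2
        _, std = standardize_annotations(a2, reference=b)
        assert std.scale["conservation"] == pytest.approx(0.5, rel=1e-9)

    def test_stored_parameters_reproduce_training_transform(self):
        rng = np.random.default_rng(2)
        a = _annotations(300, rng)
        std_df, std = standardize_annotations(a)
        again = std.transform(a)
        for col in std.mean:
            assert np.allclose(std_df[col], again[col])

    def test_zero_mean_column_errors(self):
        rng = np.random.default_rng(3)
        a = _annotations(100, rng)
        a["conservation"] = 0.0
        with pytest.raises(ValueError, match="conservation"):
            standardize_annotations(a, reference=a)


class TestGlobalModel:
    def test_no_signal_auc_near_half(self):
        rng = np.random.default_rng(4)
        a = _annotations(4000, rng)
        y = rng.random(4000) < 0.3
        std_df, _ = standardize_annotations(a)
        train, test = np.arange(2000), np.arange(2000, 4000)
        gm = fit_global_model(std_df.iloc[train], y[train])
        score = gm.predict_proba(std_df.iloc[test])
        assert abs(roc_auc_score(y[test], score) - 0.5) < 0.04

    def test_coefficient_recovery_on_known_model(self):
        rng = np.random.default_rng(5)
        n = 20_000
        a = _annotations(n, rng)
        std_df, _ = standardize_annotations(a)
        true_beta = np.zeros(13)
        true_beta[0] = 1.2   # mcv
        true_beta[9] = -0.8  # footprint
        X = std_df[list(fit_global_model.__globals__["_GLOBAL_FEATURES"])].to_numpy()
        z = X @ true_beta - 1.0
        y = rng.random(n) < 1 / (1 + np.exp(-z))
        gm = fit_global_model(std_df, y)
        # 2-SE check via asymptotic normality at this n: use a loose bound
        assert abs(gm.coef[0] - 1.2) < 0.1
        assert abs(gm.coef[9] + 0.8) < 0.1
        assert abs(gm.intercept + 1.0) < 0.1

    def test_single_class_errors(self):
        rng = np.random.default_rng(6)
        a = _annotations(100, rng)
        std_df, _ = standardize_annotations(a)
        with pytest.raises(ValueError, match="both classes"):
            fit_global_model(std_df, np.zeros(100))


class TestTFModel:
    def _rows(self, n, rng, width=10):
        return pd.DataFrame({
            "snv_id": [f"s{i}" for i in range(n)],
            "global_fit": rng.random(n),
            "score": rng.normal(12, 2, n).clip(1),
            "logodds_diff": rng.normal(0, 2, n),
            "position": rng.integers(0, width, n),
        })

    def test_planted_positions_get_largest_coefficients(self):
        rng = np.random.default_rng(7)
        rows = self._rows(4000, rng)
        y = np.isin(rows["position"], [3, 4]) & (rng.random(4000) < 0.8)
        y |= rng.random(4000) < 0.05
        m = fit_tf_model("M", rows, y)
        coefs = dict(zip(m.features, m.coef))
        pos_coefs = {f: c for f, c in coefs.items() if f.startswith("pos_")}
        top2 = sorted(pos_coefs, key=pos_coefs.get, reverse=True)[:2]
        assert set(top2) == {"pos_3", "pos_4"}
        assert pos_coefs["pos_3"] > 0 and pos_coefs["pos_4"] > 0

    def test_too_few_rows_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        rows = self._rows(20, rng)
        with pytest.warns(UserWarning, match="insufficient"):
            assert fit_tf_model("M", rows, rng.random(20) < 0.5) is None

    def test_constant_logodds_column_dropped(self):
        rng = np.random.default_rng(9)
        rows = self._rows(500, rng)
        rows["logodds_diff"] = 0.0
        with pytest.warns(UserWarning, match="logodds_diff"):
            m = fit_tf_model("M", rows, rng.random(500) < 0.5)
        assert "logodds_diff" not in m.features


class TestCombiner:
    def test_sparse_recovery_one_informative_tf(self):
        rng = np.random.default_rng(10)
        n, p = 3000, 30
        X = pd.DataFrame(rng.random((n, p)),
                         columns=[f"cluster_c{i}" for i in range(p)])
        y = rng.random(n) < 1 / (1 + np.exp(-(4 * X["cluster_c0"] - 2)))
        comb = fit_combiner(X, y, folds=10, seed=1)
        coefs = dict(zip(comb.features, comb.coef))
        assert coefs["cluster_c0"] != 0
        noise = [c for f, c in coefs.items() if f != "cluster_c0"]
        assert np.mean(np.array(noise) == 0) >= 0.9

    def test_all_noise_cv_auc_low(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.random((1000, 10)),
                         columns=[f"cluster_c{i}" for i in range(10)])
        y = rng.random(1000) < 0.3
        comb = fit_combiner(X, y, folds=5, seed=2)
        assert comb.cv_auc <= 0.55

    def test_duplicated_column_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.random((1500, 3)),
                         columns=["cluster_a", "cluster_b", "cluster_c"])
        y = rng.random(1500) < 1 / (1 + np.exp(-(3 * X["cluster_a"] - 1.5)))
        c1 = fit_combiner(X, y, folds=5, seed=3)
        X2 = X.copy()
        X2["cluster_a2"] = X["cluster_a"]
        c2 = fit_combiner(X2, y, folds=5, seed=3)
        p1 = c1.predict_proba(X)
        p2 = c2.predict_proba(X2)
        assert np.max(np.abs(p1 - p2)) < 0.02

    def test_excess_folds_reduced(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.random((40, 2)), columns=["cluster_a", "cluster_b"])
        y = np.array([0, 1] * 20)
        with pytest.warns(UserWarning, match="folds reduced"):
            fit_combiner(X, y, folds=50, seed=4)


class TestPrecisionRecall:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        _, area = precision_recall(s, y)
        assert area == pytest.approx(1.0)

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(14)
        s = rng.random(20_000)
        y = rng.random(20_000) < 0.2
        _, area = precision_recall(s, y)
        assert abs(area - 0.2) < 0.02

    def test_agrees_with_sklearn_oracle(self):
        rng = np.random.default_rng(15)
        s = rng.random(1000)
        y = (s + rng.normal(0, 0.3, 1000)) > 0.6
        curve, area = precision_recall(s, y)
        prec, rec, _ = precision_recall_curve(y.astype(int), s)
        # same curve integrated the same way (trapezoid over recall)
        skl_area = auc(rec[::-1], prec[::-1])
        assert area == pytest.approx(skl_area, abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            precision_recall([0.1, 0.9], [1, 1])


def _cato2_inputs(cohort, level="cell_type"):
    calls = call_cohort(cohort, level=level)
    per_snv = calls.groupby("snv_id")["imbalanced"].any()
    assignments = snv_motif_assignments(cohort.snvs, cohort.motif_matches)
    annotations = cohort.annotations
    return calls, per_snv, assignments, annotations


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def trained(self):
        cohort = simulate_cohort(SimConfig(seed=21, n_snvs=12_000,
                                           fraction_causal=0.08))
        calls, labels, assigns, ann = _cato2_inputs(cohort)
        bundle = train_bundle(ann, assigns, labels, seed=0, folds=5,
                              min_tf_rows=30)
        return cohort, bundle, assigns, labels

    def test_scores_bounded(self, trained):
        cohort, bundle, assigns, _ = trained
        scored = score_variants(bundle, cohort.annotations, assigns)
        assert scored["score"].between(0, 1).all()

    def test_heldout_aupr_beats_prevalence(self, trained):
        _, bundle, _, _ = trained
        held = simulate_cohort(SimConfig(seed=22, n_snvs=12_000,
                                         fraction_causal=0.08))
        calls, labels, assigns, ann = _cato2_inputs(held)
        scored = score_variants(bundle, ann, assigns)
        y = labels.reindex(scored["snv_id"]).fillna(False).to_numpy()
        _, area = precision_recall(scored["score"].to_numpy(), y)
        prevalence = y.mean()
        assert area >= 2 * prevalence

    def test_no_motif_snv_uses_global_fallback(self, trained):
        cohort, bundle, assigns, _ = trained
        no_motif = ~cohort.annotations["snv_id"].isin(assigns["snv_id"])
        ann = cohort.annotations[no_motif].head(50)
        scored = score_variants(bundle, ann, assigns.iloc[0:0])
        std = bundle.standardizer.transform(ann)
        g = bundle.global_model.predict_proba(std)
        w = dict(zip(bundle.combiner.features, bundle.combiner.coef))
        z = bundle.combiner.intercept + w["global_fit"] * g
        assert np.allclose(scored["score"], 1 / (1 + np.exp(-z)), atol=1e-9)

    def test_bundle_json_roundtrip_scores_identical(self, trained):
        cohort, bundle, assigns, _ = trained
        back = Cato2ModelBundle.from_json(bundle.to_json())
        a = score_variants(bundle, cohort.annotations, assigns)
        b = score_variants(back, cohort.annotations, assigns)
        assert np.allclose(a["score"], b["score"])

    def test_zero_weight_tf_removal_leaves_scores_unchanged(self, trained):
        import copy

        cohort, bundle, assigns, _ = trained
        # force one TF's cluster weight to zero, then drop the TF entirely:
        # scores must be identical either way
        victim = next(iter(bundle.tf_models))
        col = f"cluster_{bundle.cluster_of[victim]}"
        zeroed = copy.deepcopy(bundle)
        idx = zeroed.combiner.features.index(col)
        zeroed.combiner.coef[idx] = 0.0
        pruned = copy.deepcopy(zeroed)
        del pruned.tf_models[victim]
        a = score_variants(zeroed, cohort.annotations, assigns)
        b = score_variants(pruned, cohort.annotations, assigns)
        assert np.allclose(a["score"], b["score"])

    def test_missing_annotation_column_errors(self, trained):
        cohort, bundle, assigns, _ = trained
        with pytest.raises(ValueError, match="mcv"):
            score_variants(bundle, cohort.annotations.drop(columns=["mcv"]),
                           assigns)


class TestCellTypeSpecificity:
    def test_celltype_models_beat_aggregate_on_celltype_architecture(self):
        """With causal effects concentrated in single cell types, gated
        per-cell-type training outperforms aggregate training (sign test
        over seeds)."""
        from scipy.stats import binomtest

        from allelix.evaluation import compare_celltype_vs_aggregate

        n_seeds = 10
        wins = 0
        for seed in range(31, 31 + n_seeds):
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                a_ct, a_agg = compare_celltype_vs_aggregate(seed)
            wins += int(a_ct > a_agg)
        assert binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.05
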