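import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from metamodule import (ExpressionMatrix, PhenotypeTable,
                        RecurrenceClassifier, SyntheticCohortSpec,
                        ValidationError, cross_validate, delong_test,
                        evaluate_external, fit_logistic, multivariate_model,
                        predict_prob, roc_auc, simulate_cohort,
                        stratified_by_grade)


def brute_force_auc(scores, labels):
    """Positive-negative pair counting with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([0.5] * 8, [1, 0] * 4)
        assert r.auc == 0.5

    def test_worked_three_quarters_example(self):
        # 3 of the 4 positive-negative pairs are correctly ordered
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 50)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1.auc == pytest.approx(a2.auc, abs=1e-12)
        assert a1.se == pytest.approx(a2.se, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        r = roc_auc(rng.normal(size=30), rng.integers(0, 2, 30))
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_give_zero_z(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        res = delong_test(s, s, y)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_rank_preserving_transform_gives_p_one(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        res = delong_test(s, np.tanh(s) * 7 + 2, y)
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValidationError):
            delong_test([1, 2, 3], [1, 2], [1, 0, 1])

    def test_agrees_with_stratified_bootstrap(self):
        # paired bootstrap of the AUC difference as the independent
        # oracle for DeLong's normal approximation
        from scipy.stats import norm, rankdata

        def fast_auc(pos, neg):
            r = rankdata(np.concatenate([pos, neg]))
            return (r[:len(pos)].sum()
                    - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))

        rng = np.random.default_rng(6)
        n, n_boot, diffs_p = 300, 1500, []
        for _ in range(6):
            z = rng.normal(size=n)
            y = (rng.uniform(size=n) < expit(1.2 * z)).astype(int)
            s1 = z + rng.normal(0, 1.0, n)
            s2 = z + rng.normal(0, 1.2, n)
            res = delong_test(s1, s2, y)
            pos_idx = np.flatnonzero(y == 1)
            neg_idx = np.flatnonzero(y == 0)
            boot = np.empty(n_boot)
            for b in range(n_boot):
                pi = rng.choice(pos_idx, len(pos_idx))
                ni = rng.choice(neg_idx, len(neg_idx))
                boot[b] = fast_auc(s1[pi], s1[ni]) - fast_auc(s2[pi], s2[ni])
            # normal-theory two-sided p from the bootstrap SE
            p_boot = 2 * norm.sf(abs(res.difference) / boot.std(ddof=1))
            diffs_p.append(abs(res.p_value - p_boot))
        assert np.mean(diffs_p) < 0.05


class TestFitLogistic:
    def test_null_regressor_ci_covers_zero(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.normal(size=1000)})
        y = rng.integers(0, 2, 1000)
        model = fit_logistic(y, X)
        lo, hi = model.conf_int.loc["x"]
        assert lo < 0 < hi

    def test_matches_generic_optimizer_maximum_likelihood(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < expit(-0.5 + 1.2 * x)).astype(int)
        model = fit_logistic(y, pd.DataFrame({"x": x}))

        def negll(beta):
            eta = beta[0] + beta[1] * x
            return -(y * eta - np.logaddexp(0, eta)).sum()

        opt = minimize(negll, [0.0, 0.0], method="BFGS")
        np.testing.assert_allclose(
            [model.params["intercept"], model.params["x"]], opt.x, atol=1e-5)

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(y, X)
        assert model.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_odds_ratio_table_shape(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(size=300),
                          "b": rng.normal(size=300)})
        y = (rng.uniform(size=300) < expit(X["a"])).astype(int)
        ors = fit_logistic(y, X).odds_ratios
        assert list(ors.index) == ["a", "b"]
        assert (ors["ci_low"] <= ors["OR"]).all()
        assert (ors["OR"] <= ors["ci_high"]).all()


class TestPredictProb:
    def test_zero_model_gives_half(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.integers(0, 2, 50)
        model = fit_logistic(y, X)
        model.params[:] = 0.0
        np.testing.assert_allclose(predict_prob(model, X), 0.5)

    def test_hand_arithmetic(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.integers(0, 2, 50)
        model = fit_logistic(y, X)
        model.params["intercept"] = -1.0
        model.params["x"] = 2.0
        p = predict_prob(model, pd.DataFrame({"x": [0.5]}))
        assert p[0] == pytest.approx(0.5)

    def test_missing_regressor_rejected(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        model = fit_logistic(rng.integers(0, 2, 50), X)
        with pytest.raises(ValidationError, match="missing regressors"):
            predict_prob(model, pd.DataFrame({"y": [1.0]}))


def _leakage_probe_cohort(seed=0, n=600, genes=200, amps=(4.0, 3.0)):
    """Pure-noise cohort plus fold-specific outcome signal along two
    exactly orthogonal, variance-uniform gene directions."""
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % 2
    v = np.vstack([np.ones(genes), np.tile([1.0, -1.0], genes // 2)])
    v /= np.sqrt(genes)
    z = rng.choice([-1.0, 1.0], size=n)
    vals = rng.normal(size=(genes, n))
    for i in range(n):
        vals[:, i] += amps[folds[i]] * z[i] * v[folds[i]]
    gene_ids = [f"g{j}" for j in range(genes)]
    x = ExpressionMatrix(pd.DataFrame(
        vals, index=gene_ids, columns=[f"s{i}" for i in range(n)]))
    ph = PhenotypeTable(pd.DataFrame({
        "sample_id": x.sample_ids,
        "recurrence": ((z + 1) // 2).astype(int),
        "who_grade": 1 + (np.arange(n) % 3)}))
    return x, ph, folds, gene_ids


def _cohort(n=200, seed=0, beta1=1.75, sizes=(30,), noise=10):
    spec = SyntheticCohortSpec(n_samples=n, module_sizes=sizes,
                               n_noise_genes=noise, sigma=0.5,
                               loading_range=(1.0, 1.0), beta1=beta1,
                               seed=seed)
    return simulate_cohort(spec)


def _module_lists(truth):
    labels = truth.gene_labels
    return {"m0": list(labels.index[labels == "module0"])}


class TestCrossValidate:
    def test_leave_one_out_scores_every_sample_once(self):
        x, ph, truth = _cohort(n=10, seed=1)
        # k = n: every sample is held out exactly once
        roc = cross_validate(x, ph, _module_lists(truth), k=10, seed=0)
        assert roc.n_pos + roc.n_neg == 10

    def test_recovers_theoretical_auc_with_strong_signal(self):
        from metamodule import theoretical_auc
        x, ph, truth = _cohort(n=500, seed=2)
        spec = SyntheticCohortSpec(beta1=1.75)
        target = theoretical_auc(spec, n_draws=400_000)
        roc = cross_validate(x, ph, _module_lists(truth), k=10, seed=0)
        assert abs(roc.auc - target) < 0.05

    def test_seed_determinism(self):
        x, ph, truth = _cohort(n=120, seed=3)
        r1 = cross_validate(x, ph, _module_lists(truth), k=5, seed=42)
        r2 = cross_validate(x, ph, _module_lists(truth), k=5, seed=42)
        assert r1.auc == r2.auc

    def test_strict_mode_immune_to_heldout_only_signal(self):
        # adversarial leakage probe: each fold's samples carry outcome
        # signal along a fold-specific orthogonal gene direction, so PC1
        # loadings learned on the training fold cannot transfer it —
        # but whole-cohort PCA sees both directions and leaks
        x, ph, folds, gene_ids = _leakage_probe_cohort(seed=0)
        strict = cross_validate(x, ph, {"m": gene_ids}, k=2, seed=0,
                                mode="strict", folds=folds)
        compat = cross_validate(x, ph, {"m": gene_ids}, k=2, seed=0,
                                mode="whole-cohort", folds=folds)
        assert 0.45 <= strict.auc <= 0.55
        assert abs(compat.auc - 0.5) > 0.05


class TestExternalValidation:
    def test_identity_test_cohort_equals_resubstitution(self):
        x, ph, truth = _cohort(n=150, seed=4)
        modules = _module_lists(truth)
        roc, model = evaluate_external((x, ph), (x, ph), modules)
        from metamodule import compute_metagenes
        mg = compute_metagenes(x, modules).scores.T
        resub = roc_auc(predict_prob(model, mg), ph.recurrence.to_numpy())
        assert roc.auc == pytest.approx(resub.auc)

    def test_transfer_between_cohorts_sharing_truth(self):
        from metamodule import theoretical_auc
        xa, pa, ta = _cohort(n=400, seed=5)
        xb, pb, _ = _cohort(n=400, seed=6)
        modules = _module_lists(ta)
        cv = cross_validate(xa, pa, modules, k=10, seed=0)
        ext, _ = evaluate_external((xa, pa), (xb, pb), modules)
        # both estimates sit near the model's theoretical ceiling and,
        # within sampling error, near each other
        target = theoretical_auc(SyntheticCohortSpec(beta1=1.75),
                                 n_draws=400_000)
        assert abs(ext.auc - target) < 0.05
        assert abs(cv.auc - target) < 0.05
        assert abs(ext.auc - cv.auc) < 2.5 * (ext.se + cv.se)

    def test_mostly_missing_module_rejected(self):
        xa, pa, ta = _cohort(n=100, seed=7)
        modules = _module_lists(ta)
        keep = [g for g in xa.gene_ids if g not in modules["m0"][:25]]
        xb = xa.subset_genes(keep)
        with pytest.raises(ValidationError, match="present"):
            evaluate_external((xa, pa), (xb, pa), modules)


class TestMultivariateAndStrata:
    def test_module_stays_significant_controlling_grade(self):
        x, ph, truth = _cohort(n=400, seed=8)
        model = multivariate_model(x, ph, _module_lists(truth), "m0",
                                   covariates=("who_grade",))
        row = model.odds_ratios.loc["m0"]
        assert row["p"] < 0.05
        assert row["OR"] > 1.0

    def test_samples_missing_simpson_dropped_from_that_model_only(self):
        x, ph, truth = _cohort(n=200, seed=9)
        ph.data.loc[ph.sample_ids[0], "simpson_grade"] = np.nan
        with_sg = multivariate_model(x, ph, _module_lists(truth), "m0",
                                     covariates=("who_grade",
                                                 "simpson_grade"))
        without = multivariate_model(x, ph, _module_lists(truth), "m0",
                                     covariates=("who_grade",))
        assert with_sg.n_obs == without.n_obs - 1

    def test_grade_stratum_auc_close_to_overall(self):
        x, ph, truth = _cohort(n=1200, seed=10)
        modules = _module_lists(truth)
        overall = cross_validate(x, ph, modules, k=10, seed=0).auc
        for g in (1, 2):
            stratum = stratified_by_grade(x, ph, modules, g)
            assert abs(stratum.auc - overall) < 3.5 * stratum.se + 0.02

    def test_single_class_stratum_rejected(self):
        x, ph, truth = _cohort(n=100, seed=11)
        ph.data.loc[ph.who_grade == 3, "recurrence"] = 1
        ph.data.loc[ph.who_grade == 3, "time_to_recurrence"] = 1.0
        with pytest.raises(ValidationError, match="single outcome class"):
            stratified_by_grade(x, ph, _module_lists(truth), 3)

    def test_absent_grade_rejected(self):
        x, ph, truth = _cohort(n=60, seed=12)
        ph.data["who_grade"] = 1.0
        with pytest.raises(ValidationError):
            stratified_by_grade(x, ph, _module_lists(truth), 3)


class TestRecurrenceClassifierEstimator:
    def test_sklearn_fit_predict_interface(self):
        x, ph, truth = _cohort(n=200, seed=13)
        clf = RecurrenceClassifier(_module_lists(truth))
        frame = x.data.T
        y = ph.recurrence.to_numpy()
        clf.fit(frame, y)
        proba = clf.predict_proba(frame)
        assert proba.shape == (200, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert roc_auc(proba[:, 1], y).auc > 0.7
        assert set(clf.predict(frame)) <= {0, 1}

    def test_works_inside_sklearn_cross_val_score(self):
        from sklearn.model_selection import cross_val_score
        x, ph, truth = _cohort(n=150, seed=14)
        clf = RecurrenceClassifier(_module_lists(truth))
        scores = cross_val_score(clf, x.data.T, ph.recurrence.to_numpy(),
                                 cv=3, scoring="roc_auc")
        assert scores.mean() > 0.6
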