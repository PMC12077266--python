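import numpy as np
import pytest

import cmskit as ck
from cmskit.io import CmskitError, ExpressionMatrix, LabelVector
from cmskit.model import classify, predictions_to_labels


def _toy_training(seed=0, n_per_class=20, n_genes=2, spread=4.0, noise=0.5):
    """Two marker genes, four well-separated centroids."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [spread, 0], [0, spread], [spread, spread]], dtype=float)
    X, labels = [], []
    for k in range(4):
        X.append(centers[k] + rng.normal(0, noise, size=(n_per_class, 2)))
        labels.extend([ck.CMS_CLASSES[k]] * n_per_class)
    X = np.vstack(X)
    n = len(labels)
    sids = tuple(f"s{i}" for i in range(n))
    genes = ("G1", "G2")
    em = ExpressionMatrix(genes, sids, X.T, "log2")
    lv = LabelVector(sids, tuple(labels))
    panel = ck.GenePanel(genes, "FF")
    ref = ck.ReferenceDistribution("FF", panel, np.array([0.0, 1.0]), 2)
    tags = ("nanostring",) * n
    ts = ck.TrainingSet(X=em, y=lv, weights=np.ones(n), source=tags)
    return ts, ref, X, np.repeat(np.arange(4), n_per_class)


class TestDefaultWeights:
    def test_paper_weight_scheme(self):
        w = ck.default_weights(["nanostring", "cotraining", "cotraining"])
        np.testing.assert_array_equal(w, [1.5, 1.0, 1.0])

    def test_uniform_when_weight_is_one(self):
        w = ck.default_weights(["nanostring", "cotraining"], nanostring_weight=1.0)
        np.testing.assert_array_equal(w, [1.0, 1.0])

    def test_multiset_for_arbitrary_weight(self):
        rng = np.random.default_rng(4)
        tags = [("nanostring", "cotraining")[i] for i in rng.integers(0, 2, size=10)]
        k = tags.count("nanostring")
        w = ck.default_weights(tags, nanostring_weight=2.5)
        assert sorted(w) == sorted([2.5] * k + [1.0] * (10 - k))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(CmskitError):
            ck.default_weights(["nanostring"], nanostring_weight=0.0)


class TestFit:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        ts, ref, X, y = _toy_training()
        model = ck.fit(ts, ref, alpha=0.7, cv_folds=5, seed=1, n_lambda=15)
        eta = model.intercepts + X @ model.coefficients
        assert np.mean(eta.argmax(axis=1) == y) == 1.0

    def test_missing_class_is_error(self):
        ts, ref, _, _ = _toy_training()
        labs = tuple("CMS1" if l == "CMS2" else l for l in ts.y.labels)
        bad = ck.TrainingSet(
            X=ts.X,
            y=LabelVector(ts.y.sample_ids, labs),
            weights=ts.weights,
            source=ts.source,
        )
        with pytest.raises(CmskitError, match="CMS2"):
            ck.fit(bad, ref, alpha=0.7, seed=0)

    def test_lambda_zero_limit_matches_unpenalized_mle(self):
        """Against the statsmodels multinomial MLE on small noisy data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n, p = 200, 5
        y = np.repeat([0, 1, 2, 3], 50)
        centers = rng.normal(0, 0.8, size=(4, p))
        X = centers[y] + rng.normal(0, 1.2, size=(n, p))
        sids = tuple(f"s{i}" for i in range(n))
        genes = tuple(f"G{j}" for j in range(p))
        em = ExpressionMatrix(genes, sids, X.T, "log2")
        lv = LabelVector(sids, tuple(ck.CMS_CLASSES[k] for k in y))
        panel = ck.GenePanel(genes, "FF")
        ref = ck.ReferenceDistribution("FF", panel, np.sort(rng.normal(size=p)), 2)
        ts = ck.TrainingSet(X=em, y=lv, weights=np.ones(n), source=("nanostring",) * n)
        model = ck.fit(ts, ref, alpha=0.5, lambda_grid=[1e-10], seed=0)

        mle = sm.MNLogit(y, sm.add_constant(X)).fit(disp=0, method="newton")
        eta_sm = sm.add_constant(X) @ mle.params  # eta_k - eta_0, k = 1..3
        eta = model.intercepts + X @ model.coefficients
        diffs = eta[:, 1:] - eta[:, [0]]
        assert np.abs(diffs - eta_sm).max() < 1e-3

    def test_doubling_weights_gives_identical_classifications(self):
        ts, ref, X, y = _toy_training(seed=5)
        grid = [0.05]
        m1 = ck.fit(ts, ref, alpha=0.5, lambda_grid=grid, seed=2)
        ts2 = ck.TrainingSet(
            X=ts.X, y=ts.y, weights=ts.weights * 2.0, source=ts.source
        )
        m2 = ck.fit(ts2, ref, alpha=0.5, lambda_grid=grid, seed=2)
        e1 = (m1.intercepts + X @ m1.coefficients).argmax(axis=1)
        e2 = (m2.intercepts + X @ m2.coefficients).argmax(axis=1)
        np.testing.assert_array_equal(e1, e2)

    def test_seed_determinism_bit_identical_model_file(self, tmp_path):
        ts, ref, _, _ = _toy_training(seed=6)
        m1 = ck.fit(ts, ref, alpha=0.7, cv_folds=5, seed=9, n_lambda=10)
        m2 = ck.fit(ts, ref, alpha=0.7, cv_folds=5, seed=9, n_lambda=10)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        ck.save_model(m1, str(p1))
        ck.save_model(m2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_nonzero_count_nonincreasing_in_lambda(self, small_model):
        nz = small_model.training_meta["nonzero_path"]
        assert all(a <= b for a, b in zip(nz, nz[1:]))


class TestPredictProba:
    def _zero_model(self, intercepts):
        panel = ck.GenePanel(("G1", "G2"), "FF")
        ref = ck.ReferenceDistribution("FF", panel, np.array([0.0, 1.0]), 2)
        return ck.CMSModel(
            panel=panel,
            fixation="FF",
            alpha=0.7,
            lambda_=0.1,
            intercepts=np.asarray(intercepts, dtype=float),
            coefficients=np.zeros((2, 4)),
            reference=ref,
        )

    def test_symmetric_model_gives_uniform_probs(self):
        m = self._zero_model([0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            ck.predict_proba(m, np.array([3.0, 1.0])), [0.25] * 4, atol=1e-12
        )

    def test_log2_intercept_gives_closed_form_softmax(self):
        m = self._zero_model([np.log(2.0), 0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            ck.predict_proba(m, np.array([3.0, 1.0])), [0.4, 0.2, 0.2, 0.2], atol=1e-12
        )

    def test_matches_naive_softmax_oracle(self, small_model, small_cohort):
        matrix, _, _ = small_cohort
        for j in range(10):
            x = matrix.values[:, j]
            probs = ck.predict_proba(small_model, x)
            from cmskit.normalize import quantile_normalize_sample

            xn = quantile_normalize_sample(x, small_model.reference)
            eta = small_model.intercepts + xn @ small_model.coefficients
            oracle = np.exp(eta - eta.max())
            oracle /= oracle.sum()
            np.testing.assert_allclose(probs, oracle, atol=1e-12)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_shift_of_sample_does_not_change_prediction(
        self, small_model, small_cohort
    ):
        matrix, _, _ = small_cohort
        x = matrix.values[:, 0]
        np.testing.assert_array_equal(
            ck.predict_proba(small_model, x), ck.predict_proba(small_model, x + 11.3)
        )

    def test_perform_log2_path_equals_manual_transform(self, small_model):
        rng = np.random.default_rng(3)
        counts = rng.uniform(0, 1000, size=len(small_model.panel))
        a = ck.predict_proba(small_model, counts, perform_log2=True)
        b = ck.predict_proba(small_model, np.log2(counts + 1.0))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "probs,threshold,label,confidence",
        [
            ((0.70, 0.20, 0.05, 0.05), 0.6, "CMS1", 0.50),
            ((0.55, 0.25, 0.10, 0.10), 0.6, "NA", 0.30),
            ((0.25, 0.25, 0.25, 0.25), 0.6, "NA", 0.0),
        ],
    )
    def test_threshold_and_confidence(self, probs, threshold, label, confidence):
        got_label, max_prob, got_conf, _ = classify(probs, threshold)
        assert got_label == label
        assert got_conf == pytest.approx(confidence, abs=1e-12)
        assert max_prob == pytest.approx(max(probs))

    def test_argmax_tie_flagged_and_broken_by_class_order(self):
        label, _, conf, tied = classify((0.45, 0.45, 0.05, 0.05), threshold=0.4)
        assert label == "CMS1" and tied and conf == pytest.approx(0.0)

    @pytest.mark.parametrize("threshold", [0.25, 0.2, 1.01])
    def test_threshold_domain_enforced(self, threshold):
        with pytest.raises(CmskitError, match="threshold"):
            classify((0.7, 0.1, 0.1, 0.1), threshold)

    def test_confident_set_shrinks_with_threshold(self, small_model, small_cohort):
        matrix, _, _ = small_cohort
        fractions = []
        for thr in np.arange(0.3, 0.91, 0.1):
            preds = ck.predict_matrix(small_model, matrix, threshold=float(thr))
            fractions.append(np.mean([p.label != "NA" for p in preds]))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
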