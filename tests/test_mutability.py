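"""Feature-matrix construction, elastic-net training, calibration,
cross-prediction and the binary C→T classifier."""
import subprocess

import numpy as np
import pandas as pd
import pytest

from mamut import mutability as mb
from mamut.mutability import (MutabilityModel, Scaler, build_feature_matrix,
                              calibrate_predictions, cross_predict,
                              encode_features, train_ct_classifier,
                              train_mutability)


def _numeric_features(n, p=6, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    df = pd.DataFrame(X, columns=[f"E_{i}" for i in range(p)])
    if effect is None:
        y = rng.integers(0, 2, n)
    else:
        logit = X @ effect
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return df, y


class TestFeatureMatrix:
    def test_constant_column_removed_by_scaler(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [5.0, 5.0, 5.0, 5.0]})
        scaler = Scaler.fit(df)
        assert scaler.columns == ["a"]

    def test_test_rows_scaled_by_training_stats(self):
        train = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        test = pd.DataFrame({"a": [100.0]})
        scaler = Scaler.fit(train)
        z = scaler.transform(test)
        assert z[0, 0] == pytest.approx((100 - 2.0) / train["a"].std(ddof=0))

    def test_triplet_slots_encode_32_indicators(self):
        from mamut.seqcontext import canonical_triplets
        rows = []
        for up in canonical_triplets("up"):
            rows.append({"up_ctx": up, "mid_ctx": "GAT", "down_ctx": "ATA",
                         "E_2": 0.5})
        frame = encode_features(pd.DataFrame(rows))
        up_cols = [c for c in frame.columns if c.startswith("up_ctx_")]
        assert len(up_cols) == 32

    def test_missing_rows_dropped(self):
        df = pd.DataFrame({"E_2": [0.1, np.nan, 0.3],
                           "up_ctx": ["AAA", "AAC", ""],
                           "mid_ctx": ["GAT"] * 3,
                           "down_ctx": ["ATA"] * 3})
        matrix = build_feature_matrix(df, [1, 0, 1])
        assert len(matrix.frame) == 1
        assert matrix.y.tolist() == [1]

    def test_label_misalignment_error(self):
        df, _ = _numeric_features(10)
        with pytest.raises(ValueError):
            build_feature_matrix(df, [0, 1])


class TestTrainMutability:
    def test_deterministic_for_fixed_seed(self):
        df, y = _numeric_features(300, effect=np.r_[2.0, np.zeros(5)])
        matrix = build_feature_matrix(df, y)
        kw = dict(n_nonmutated=150, cv_folds=3, replicates=2,
                  cs=np.logspace(-2, 1, 3), seed=4)
        m1 = train_mutability(matrix, **kw)
        m2 = train_mutability(matrix, **kw)
        for r1, r2 in zip(m1.replicates, m2.replicates):
            assert np.allclose(r1.coef, r2.coef)

    def test_recovers_planted_numeric_effect(self):
        df, y = _numeric_features(600, effect=np.r_[2.0, np.zeros(5)],
                                  seed=1)
        matrix = build_feature_matrix(df, y)
        model = train_mutability(matrix, n_nonmutated=1000, cv_folds=4,
                                 replicates=4, cs=np.logspace(-2, 1, 3),
                                 seed=2)
        summ = model.coefficient_summary()
        assert summ.loc["E_0", "median"] > 0
        assert summ.loc["E_0", "ci_low"] > 0
        # sign stability across replicates for the planted strong effect
        signs = [np.sign(r.coef["E_0"]) for r in model.replicates]
        assert sum(s > 0 for s in signs) == len(signs)

    def test_noise_labels_coefficients_cover_zero(self):
        df, y = _numeric_features(500, p=12, seed=3)
        matrix = build_feature_matrix(df, y)
        model = train_mutability(matrix, n_nonmutated=400, cv_folds=4,
                                 replicates=4, cs=np.logspace(-2, 0, 3),
                                 seed=5)
        summ = model.coefficient_summary()
        covered = ((summ["ci_low"] <= 0) & (summ["ci_high"] >= 0)).mean()
        assert covered >= 0.9

    def test_single_class_error(self):
        df, _ = _numeric_features(50)
        matrix = build_feature_matrix(df, np.ones(50))
        with pytest.raises(ValueError):
            train_mutability(matrix, replicates=1)

    def test_serialization_round_trip(self):
        df, y = _numeric_features(200, effect=np.r_[1.0, np.zeros(5)])
        matrix = build_feature_matrix(df, y)
        model = train_mutability(matrix, n_nonmutated=100, cv_folds=3,
                                 replicates=2, cs=[0.1, 1.0], seed=0)
        restored = MutabilityModel.from_frame(model.to_frame())
        p1 = model.predict_proba(matrix.frame)
        p2 = restored.predict_proba(matrix.frame)
        assert np.allclose(p1, p2, atol=1e-9)

    def test_agrees_with_glmnet_at_fixed_penalty(self):
        """Independent oracle: R glmnet at the matched lambda."""
        rng = np.random.default_rng(0)
        n, p = 400, 5
        X = rng.normal(size=(n, p))
        beta = np.r_[1.0, -0.5, 0.0, 0.0, 0.3]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        Xs = (X - X.mean(0)) / X.std(0)
        C = 0.5
        from sklearn.linear_model import LogisticRegression
        m = LogisticRegression(solver="saga", l1_ratio=0.5, C=C,
                               max_iter=20_000, tol=1e-8).fit(Xs, y)
        script = """
        suppressMessages(library(glmnet))
        X <- matrix(scan('stdin', quiet=TRUE), ncol=%d, byrow=TRUE)
        y <- X[, %d]
        X <- X[, 1:%d]
        fit <- glmnet(X, y, family='binomial', alpha=0.5, lambda=%.10f,
                      standardize=FALSE, thresh=1e-12)
        cat(as.numeric(coef(fit)), sep=',')
        """ % (p + 1, p + 1, p, 1 / (C * n))
        payload = "\n".join(" ".join(f"{v:.10f}" for v in row)
                            for row in np.column_stack([Xs, y]))
        try:
            out = subprocess.run(["Rscript", "-e", script],
                                 input=payload, capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        coefs_r = np.fromstring(out.stdout, sep=",")
        ours = np.r_[m.intercept_, m.coef_.ravel()]
        assert np.allclose(ours, coefs_r, atol=5e-3)


class TestCalibration:
    def _fitted(self, seed=0):
        df, y = _numeric_features(2000, effect=np.r_[1.5, -1.0,
                                                     np.zeros(4)],
                                  seed=seed)
        matrix = build_feature_matrix(df, y)
        model = train_mutability(matrix, n_nonmutated=2000, cv_folds=3,
                                 replicates=2, cs=[1.0], seed=1)
        return model, matrix

    def test_well_specified_model_calibrates(self):
        model, matrix = self._fitted()
        calib = calibrate_predictions(model, matrix.frame, matrix.y)
        assert calib.slope > 0
        assert calib.r2 > 0.9

    def test_constant_predictor_single_bin(self):
        df = pd.DataFrame({"E_0": np.zeros(50), "E_1": np.ones(50)})
        scaler = Scaler(columns=["E_0"], mean=np.array([0.0]),
                        sd=np.array([1.0]))
        rep = mb.ReplicateFit(scaler=scaler,
                              coef=pd.Series([0.0], index=["E_0"]),
                              intercept=0.0, C=1.0, seed=0)
        model = MutabilityModel(l1_ratio=0.5, replicates=[rep],
                                n_mutated=0, n_nonmutated=0, seed=0)
        calib = calibrate_predictions(model, df, np.zeros(50))
        assert len(calib.table) == 1
        assert np.isnan(calib.slope)

    def test_shuffled_labels_destroy_fit(self):
        model, matrix = self._fitted(seed=2)
        rng = np.random.default_rng(3)
        r2s = []
        for _ in range(20):
            y_shuf = rng.permutation(matrix.y)
            r2s.append(calibrate_predictions(model, matrix.frame,
                                             y_shuf).r2)
        assert np.median(r2s) < 0.2


class TestCrossPredict:
    def test_self_prediction_identical(self):
        df, y = _numeric_features(500, effect=np.r_[1.0, np.zeros(5)])
        matrix = build_feature_matrix(df, y)
        model = train_mutability(matrix, n_nonmutated=400, cv_folds=3,
                                 replicates=2, cs=[1.0], seed=0)
        own = calibrate_predictions(model, matrix.frame, matrix.y)
        crossed, mismatches = cross_predict(model, matrix.frame, matrix.y)
        assert mismatches == []
        assert crossed.slope == pytest.approx(own.slope)

    def test_shared_generative_model_crosses_over(self):
        effect = np.r_[1.5, -1.0, np.zeros(4)]
        df_a, y_a = _numeric_features(1500, effect=effect, seed=10)
        df_b, y_b = _numeric_features(1500, effect=effect, seed=11)
        model = train_mutability(build_feature_matrix(df_a, y_a),
                                 n_nonmutated=1500, cv_folds=3,
                                 replicates=2, cs=[1.0], seed=1)
        crossed, _ = cross_predict(model, df_b, y_b)
        assert crossed.slope > 0
        assert crossed.p < 0.05

    def test_disjoint_schema_error(self):
        df, y = _numeric_features(200, effect=np.r_[1.0, np.zeros(5)])
        model = train_mutability(build_feature_matrix(df, y),
                                 n_nonmutated=150, cv_folds=3,
                                 replicates=1, cs=[1.0], seed=0)
        other = pd.DataFrame({"zzz": np.zeros(5)})
        with pytest.raises(ValueError):
            cross_predict(model, other, np.zeros(5))


class TestCtClassifier:
    def _snm_features(self, n=600, separable=True, seed=0):
        rng = np.random.default_rng(seed)
        is_ct = rng.random(n) < 0.5
        e2 = np.where(is_ct, 1.0, -1.0) if separable \
            else rng.normal(size=n)
        df = pd.DataFrame({
            "E_2": e2 + 0.01 * rng.normal(size=n),
            "L_2": rng.normal(size=n),
            "up_ctx": rng.choice(["ATA", "CTC", "GGA"], size=n),
            "mid_ctx": rng.choice(["GAT", "ACA"], size=n),
            "down_ctx": rng.choice(["ATA", "CGG"], size=n),
        })
        refs = np.where(is_ct, "C", "A")
        alts = np.where(is_ct, "T", "G")
        return df, refs, alts

    def test_separable_fixture_high_accuracy(self):
        df, refs, alts = self._snm_features(separable=True)
        res = train_ct_classifier(df, refs, alts, cv_folds=3,
                                  cs=[1.0], seed=1)
        assert res.accuracy > 0.9
        assert res.p < 1e-6

    def test_gc_columns_excluded(self):
        df, refs, alts = self._snm_features()
        df["GC_2"] = 1.0 * (refs == "C")   # would leak the label
        res = train_ct_classifier(df, refs, alts, cv_folds=3, cs=[1.0],
                                  seed=1)
        assert not any(c.startswith("GC_") for c in res.coef.index)

    @pytest.mark.parametrize("balancing", ["down", "up", "smote"])
    def test_balancing_strategies_run(self, balancing):
        df, refs, alts = self._snm_features(n=400, separable=True, seed=2)
        res = train_ct_classifier(df, refs, alts, balancing=balancing,
                                  cv_folds=3, cs=[1.0], seed=3)
        assert res.accuracy > 0.8
        assert res.balancing == balancing

    def test_single_class_error(self):
        df, refs, alts = self._snm_features(n=100)
        with pytest.raises(ValueError):
            train_ct_classifier(df, np.array(["C"] * 100),
                                np.array(["T"] * 100), seed=0)
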