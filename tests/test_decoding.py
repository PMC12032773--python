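"""CSP against brute-force/MNE oracles, feature properties, CV schemes, CNN."""

import numpy as np
import pytest
from scipy import linalg

from exobci.config import CNNConfig, CSPConfig
from exobci.cnn import CompactCNN, CompactCNNDecoder
from exobci.decoding import (
    CSPLDADecoder,
    cross_subject_cv,
    csp_features,
    csp_fit,
    within_subject_cv,
)


def toy_trials(rng, n_per_class, n_ch, boost_ch_a=0, boost_ch_b=1, scale=3.0):
    """Two classes whose variance concentrates on different channels."""
    Xa = rng.standard_normal((n_per_class, n_ch, 128))
    Xb = rng.standard_normal((n_per_class, n_ch, 128))
    Xa[:, boost_ch_a, :] *= scale
    Xb[:, boost_ch_b, :] *= scale
    X = np.concatenate([Xa, Xb])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


def subspace_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle (sine) between the row spaces of a and b.

    Computed from the orthogonal residual, which stays well-conditioned for
    angles near zero (arccos of the smallest singular value loses precision).
    """
    qa = linalg.orth(a.T)
    qb = linalg.orth(b.T)
    resid = qb - qa @ (qa.T @ qb)
    return float(linalg.svdvals(resid).max())


class TestCSP:
    def test_matches_brute_force_generalized_eigensolve(self):
        """Filters span the same space as eig(inv(C0+C1) @ C0) extremes."""
        rng = np.random.default_rng(0)
        X, y = toy_trials(rng, 40, 4)
        cfg = CSPConfig(n_filters=2, ridge=0.0)
        model = csp_fit(X, y, cfg, fit_lda=False)

        # brute-force oracle: explicit covariance averaging and plain eig
        def cov(trials):
            cs = [t @ t.T / np.trace(t @ t.T) for t in trials]
            return np.mean(cs, axis=0)

        c0, c1 = cov(X[y == 0]), cov(X[y == 1])
        evals, evecs = np.linalg.eig(np.linalg.inv(c0 + c1) @ c0)
        order = np.argsort(evals.real)
        oracle = np.real(evecs[:, [order[0], order[-1]]]).T
        assert subspace_angle(model.filters, oracle) < 1e-8

    def test_matches_mne_csp_pattern_space(self):
        """Independent cross-check against MNE's CSP decomposition."""
        from mne.decoding import CSP as MNECSP

        rng = np.random.default_rng(1)
        X, y = toy_trials(rng, 60, 6)
        model = csp_fit(X, y, CSPConfig(n_filters=2, ridge=0.0), fit_lda=False)
        mne_csp = MNECSP(n_components=2, reg=None, norm_trace=True,
                         cov_est="epoch", component_order="mutual_info")
        mne_csp.fit(X, y)
        # conventions differ slightly (per-trial vs. averaged trace
        # normalization), so agreement is close but not to machine precision
        assert subspace_angle(model.filters, mne_csp.filters_[:2]) < 0.05

    def test_filters_align_with_variance_axes(self):
        rng = np.random.default_rng(2)
        X, y = toy_trials(rng, 200, 3, scale=6.0)
        model = csp_fit(X, y, CSPConfig(n_filters=2), fit_lda=False)
        # extreme-eigenvalue filters point (mostly) at channels 0 and 1
        dominant = {np.argmax(np.abs(f)) for f in model.filters}
        assert dominant == {0, 1}
        assert model.eigenvalues[0] < 0.2 and model.eigenvalues[-1] > 0.8

    def test_identical_classes_are_chance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 4, 128))
        y = np.array([0, 1] * 40)
        model = csp_fit(X, y, CSPConfig(n_filters=2))
        assert np.all(np.abs(model.eigenvalues - 0.5) < 0.1)
        res = within_subject_cv(X, y, lambda: CSPLDADecoder(CSPConfig(channels=None)),
                                k=5, seed=0)
        assert 25 < res.mean_accuracy < 75

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X, y = toy_trials(rng, 50, 5)
        perm = rng.permutation(5)
        m1 = csp_fit(X, y, CSPConfig(n_filters=2), fit_lda=False)
        m2 = csp_fit(X[:, perm, :], y, CSPConfig(n_filters=2), fit_lda=False)
        assert subspace_angle(m1.filters[:, perm], m2.filters) < 1e-8


class TestCSPFeatures:
    def test_normalized_variances_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, y = toy_trials(rng, 30, 4)
        model = csp_fit(X, y, CSPConfig(n_filters=2))
        feats = csp_features(model, X)
        assert np.allclose(np.exp(feats).sum(axis=1), 1.0)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(6)
        X, y = toy_trials(rng, 30, 4)
        model = csp_fit(X, y, CSPConfig(n_filters=2))
        assert np.allclose(csp_features(model, X), csp_features(model, 2.0 * X))

    def test_zero_variance_trial_rejected(self):
        rng = np.random.default_rng(7)
        X, y = toy_trials(rng, 30, 4)
        model = csp_fit(X, y, CSPConfig(n_filters=2))
        X[0] = 0.0
        with pytest.raises(ValueError):
            csp_features(model, X)


class TestCVSchemes:
    def test_within_kfold_partitions_every_trial(self):
        rng = np.random.default_rng(8)
        X, y = toy_trials(rng, 25, 3)

        seen = []

        class Recorder:
            def fit(self, X, y):
                return self

            def predict(self, Xt):
                seen.append(Xt)
                return np.zeros(len(Xt))

        res = within_subject_cv(X, y, Recorder, k=10, seed=0, mode="kfold")
        assert len(res.fold_accuracies) == 10
        assert sum(len(s) for s in seen) == len(y)

    def test_constant_predictor_is_chance_on_balanced_data(self):
        rng = np.random.default_rng(9)
        X, y = toy_trials(rng, 30, 3)

        class Constant:
            def fit(self, X, y):
                return self

            def predict(self, Xt):
                return np.zeros(len(Xt))

        res = within_subject_cv(X, y, Constant, k=10, seed=1, mode="kfold")
        assert res.mean_accuracy == pytest.approx(50.0, abs=1e-9)

    def test_cross_subject_no_identity_leakage_and_sp_fold_count(self):
        rng = np.random.default_rng(10)
        subj = {}
        for s in range(10):
            X, y = toy_trials(rng, 10, 3)
            subj[f"SP-{s}"] = (X, y)

        tested = []

        class Probe:
            def fit(self, X, y):
                self.n_train = len(X)
                return self

            def predict(self, Xt):
                tested.append(len(Xt))
                return np.zeros(len(Xt))

        res = cross_subject_cv(subj, Probe, population="SP", seed=0)
        assert len(res.fold_accuracies) == 10  # leave-one-subject-out
        assert all(n == 20 for n in tested)    # exactly one subject per test fold

        res_hs = cross_subject_cv(subj, Probe, population="HS", seed=0,
                                  n_repeats=4, n_test_subjects=2)
        assert len(res_hs.fold_accuracies) == 4

    def test_population_too_small(self):
        rng = np.random.default_rng(11)
        X, y = toy_trials(rng, 5, 3)
        with pytest.raises(ValueError):
            cross_subject_cv({"a": (X, y)}, lambda: None, population="HS", seed=0)


class TestCompactCNN:
    def test_parameter_count_matches_arithmetic(self):
        cfg = CNNConfig(f1=8, depth_multiplier=2, f2=16, temporal_kernel=101,
                        separable_kernel=17, pool1=4, pool2=8)
        C, T = 64, 700
        net = CompactCNN(cfg, n_channels=C, n_times=T, seed=0)
        M = cfg.f1 * cfg.depth_multiplier
        t2 = (T // cfg.pool1) // cfg.pool2
        expected = (
            cfg.f1 * cfg.temporal_kernel + 2 * cfg.f1          # temporal conv + BN
            + M * C + 2 * M                                    # depthwise spatial + BN
            + M * cfg.separable_kernel + M * cfg.f2 + 2 * cfg.f2  # separable + BN
            + cfg.f2 * t2 * 2 + 2                              # dense head
        )
        assert net.n_parameters == expected

    def test_untrained_model_is_chance(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 8, 160))
        y = np.array([0, 1] * 30)
        cfg = CNNConfig(f1=4, depth_multiplier=2, f2=8, temporal_kernel=17,
                        separable_kernel=9, pool1=4, pool2=4, epochs=0)
        dec = CompactCNNDecoder(cfg, seed=0).fit(X, y)
        acc = (dec.predict(X) == y).mean()
        # binomial 99% CI around 0.5 at n=60
        assert 0.30 < acc < 0.70

    def test_learns_strongly_separable_classes(self):
        """Large class-dependent oscillatory amplitude -> >90% train accuracy."""
        rng = np.random.default_rng(13)
        t = np.arange(200) / 200.0
        osc = np.sin(2 * np.pi * 10 * t)
        X = rng.standard_normal((100, 8, 200))
        y = np.array([0, 1] * 50)
        X[y == 0, 0] += 5 * osc * rng.standard_normal((50, 1))
        X[y == 1, 1] += 5 * osc * rng.standard_normal((50, 1))
        cfg = CNNConfig(f1=4, depth_multiplier=2, f2=8, temporal_kernel=25,
                        separable_kernel=9, pool1=4, pool2=4, epochs=40,
                        batch_size=25)
        dec = CompactCNNDecoder(cfg, seed=0).fit(X, y)
        assert (dec.predict(X) == y).mean() > 0.9

    def test_training_is_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((40, 4, 120))
        y = np.array([0, 1] * 20)
        cfg = CNNConfig(f1=2, depth_multiplier=2, f2=4, temporal_kernel=9,
                        separable_kernel=5, pool1=4, pool2=4, epochs=3)
        p1 = CompactCNNDecoder(cfg, seed=5).fit(X, y).predict_proba(X)
        p2 = CompactCNNDecoder(cfg, seed=5).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)
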