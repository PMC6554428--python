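"""CSP/CICSP spatial filtering, feature extraction, and classification."""

import numpy as np
import pytest

from conftest import as_window
from mmbci import cicsp, synth
from mmbci.types import EEGRecording, LabeledTrialSet

FS = 250.0


def noise_trials(n_per_class, n_samples, n_ch=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = tuple(f"ch{i}" for i in range(n_ch))
    trials = []
    for _ in range(n_per_class):
        for lab in ("left", "right"):
            trials.append((EEGRecording(rng.standard_normal((n_ch, n_samples)),
                                        labels, FS), lab))
    return LabeledTrialSet(trials)


class TestClassCovariances:
    def test_trace_normalized(self):
        trials = noise_trials(3, 200)
        C1, C2 = cicsp.class_covariances(trials)
        assert np.trace(C1) == pytest.approx(1.0, abs=1e-12)
        assert np.trace(C2) == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_near_identity(self):
        trials = noise_trials(1, 10_000, n_ch=4, seed=1)
        C1, _ = cicsp.class_covariances(trials)
        np.testing.assert_allclose(C1, np.eye(4) / 4, atol=0.025)  # 10% of 1/C

    def test_duplicated_trials_identical(self):
        trials = noise_trials(2, 200, seed=2)
        a = cicsp.class_covariances(trials)
        b = cicsp.class_covariances(
            LabeledTrialSet(trials.trials + trials.trials))
        np.testing.assert_allclose(a[0], b[0], atol=1e-14)

    def test_missing_class_rejected(self):
        trials = noise_trials(2, 200)
        only_left = LabeledTrialSet(
            [(r, l) for r, l in trials if l == "left"])
        with pytest.raises(ValueError):
            cicsp.class_covariances(only_left, ("left", "right"))


class TestSolveCSP:
    def test_2x2_closed_form(self):
        C1 = np.diag([2.0, 1.0]) / 3.0
        C2 = np.diag([1.0, 2.0]) / 3.0
        bank = cicsp.solve_csp(C1, C2)
        np.testing.assert_allclose(bank.eigvals, [2 / 3, 1 / 3], atol=1e-6)
        # filters align with the coordinate axes up to sign/scale
        for row, axis in zip(bank.W, np.eye(2)):
            cos = abs(row @ axis) / np.linalg.norm(row)
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_equal_covariances_give_half_eigvals(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 5))
        C = A @ A.T
        C /= np.trace(C)
        bank = cicsp.solve_csp(C, C)
        np.testing.assert_allclose(bank.eigvals, 0.5, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_whitening_identity_on_random_spd_pairs(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        C1 = A @ A.T / np.trace(A @ A.T)
        C2 = B @ B.T / np.trace(B @ B.T)
        bank = cicsp.solve_csp(C1, C2)
        np.testing.assert_allclose(bank.W @ (C1 + C2) @ bank.W.T,
                                   np.eye(6), atol=1e-6)

    def test_simultaneous_diagonalization(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        C1 = A @ A.T / np.trace(A @ A.T)
        C2 = B @ B.T / np.trace(B @ B.T)
        bank = cicsp.solve_csp(C1, C2)
        for C in (C1, C2):
            P = bank.W @ C @ bank.W.T
            off = P - np.diag(np.diag(P))
            assert np.abs(off).max() < 1e-6

    def test_top_filter_maximizes_rayleigh_quotient(self):
        rng = np.random.default_rng(17)
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        C1 = A @ A.T / np.trace(A @ A.T)
        C2 = B @ B.T / np.trace(B @ B.T)
        bank = cicsp.solve_csp(C1, C2)
        w0 = bank.W[0]
        best = (w0 @ C1 @ w0) / (w0 @ (C1 + C2) @ w0)
        draws = rng.standard_normal((10_000, 6))
        draws /= np.linalg.norm(draws, axis=1, keepdims=True)
        rq = np.einsum("ij,jk,ik->i", draws, C1, draws) / \
            np.einsum("ij,jk,ik->i", draws, C1 + C2, draws)
        assert rq.max() <= best + 1e-6


class TestLogvarFeatures:
    def test_equal_power_rows(self):
        Z = np.vstack([np.ones(100), -np.ones(100)])
        np.testing.assert_allclose(cicsp.logvar_features(Z), np.log(0.5),
                                   atol=1e-12)

    def test_exp_features_sum_to_one(self):
        Z = np.random.default_rng(4).standard_normal((5, 200))
        lam = cicsp.logvar_features(Z)
        assert np.exp(lam).sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        Z = np.random.default_rng(5).standard_normal((3, 100))
        np.testing.assert_allclose(cicsp.logvar_features(Z),
                                   cicsp.logvar_features(10.0 * Z), atol=1e-12)

    def test_zero_power_row_clamped(self):
        Z = np.vstack([np.ones(50), np.zeros(50)])
        lam = cicsp.logvar_features(Z)
        assert lam[1] == pytest.approx(np.log(1e-12))


class TestFitPredict:
    def test_feature_dimension(self, mi_model):
        assert mi_model.n_features == 2 * 2 + 1 == 5
        assert mi_model.Q1.shape[0] == 4
        assert mi_model.Q2.shape[0] == 6
        assert mi_model.clf_w.shape == (5,)

    def test_no_intermediate_filters_left_rejected(self, fast_cfg):
        trials = synth.make_mi_trials(4, fast_cfg)
        with pytest.raises(ValueError):
            cicsp.fit_cicsp(trials, m=5, k=1)

    def test_held_out_accuracy_at_deep_erd(self, mi_model):
        """Parameter recovery: strong lateralized ERD is decoded at >=90%."""
        test = synth.make_mi_trials(20, synth.SynthConfig(fs=FS, seed=7000))
        acc = np.mean([cicsp.predict_mi(rec, mi_model) == lab
                       for rec, lab in test])
        assert acc >= 0.90

    def test_chance_level_without_erd(self, mi_model):
        null_cfg = synth.SynthConfig(fs=FS, seed=7500, erd_depth=0.0)
        test = synth.make_mi_trials(20, null_cfg)
        acc = np.mean([cicsp.predict_mi(rec, mi_model) == lab
                       for rec, lab in test])
        assert 0.35 <= acc <= 0.65

    def test_online_prediction_matches_intent(self, mi_model):
        cfg = synth.SynthConfig(fs=FS, seed=8000)
        rec = synth.generate_background(cfg)
        rec = synth.inject_mi_erd(rec, "left", cfg.erd_depth)
        assert cicsp.predict_mi_online(as_window(rec), mi_model) == "left"

    def test_online_invariant_to_amplitude_scale(self, mi_model):
        cfg = synth.SynthConfig(fs=FS, seed=8001)
        rec = synth.generate_background(cfg)
        rec = synth.inject_mi_erd(rec, "right", cfg.erd_depth)
        a = cicsp.predict_mi_online(as_window(rec), mi_model)
        scaled = rec.copy()
        scaled.data *= 30.0
        assert cicsp.predict_mi_online(as_window(scaled), mi_model) == a

    def test_online_wrong_length_rejected(self, mi_model):
        cfg = synth.SynthConfig(fs=FS, duration_s=1.0, seed=8002)
        rec = synth.generate_background(cfg)
        with pytest.raises(ValueError):
            cicsp.predict_mi_online(as_window(rec), mi_model)

    def test_batch_online_agreement(self, mi_model):
        """Online sub-windowing may only rarely flip a high-SNR decision."""
        test = synth.make_mi_trials(20, synth.SynthConfig(fs=FS, seed=8100))
        agree = np.mean([
            cicsp.predict_mi(rec, mi_model)
            == cicsp.predict_mi_online(as_window(rec), mi_model)
            for rec, _ in test
        ])
        assert agree >= 0.85

    def test_accuracy_monotone_in_erd_depth(self):
        """More ERD, better decoding (2% slack for simulation noise)."""
        accs = []
        for depth in (0.0, 0.3, 0.6, 0.9):
            cfg = synth.SynthConfig(fs=FS, seed=40, erd_depth=depth)
            model = cicsp.fit_cicsp(synth.make_mi_trials(25, cfg))
            test_cfg = synth.SynthConfig(fs=FS, seed=41, erd_depth=depth)
            test = synth.make_mi_trials(25, test_cfg)
            accs.append(np.mean([cicsp.predict_mi(r, model) == l
                                 for r, l in test]))
        for lo, hi in zip(accs, accs[1:]):
            assert hi >= lo - 0.02

    def test_cicsp_not_worse_than_plain_csp(self):
        """The extra PCA-reduced intermediate feature must not cost
        accuracy on data whose variance structure spans the middle
        eigenvectors (moderate, non-saturating ERD)."""
        cicsp_accs, csp_accs = [], []
        for seed in range(3):
            cfg = synth.SynthConfig(fs=FS, seed=60 + seed, erd_depth=0.35)
            train = synth.make_mi_trials(25, cfg)
            test = synth.make_mi_trials(
                25, synth.SynthConfig(fs=FS, seed=600 + seed, erd_depth=0.35))
            full = cicsp.fit_cicsp(train, m=2, k=1)
            plain = cicsp.fit_cicsp(train, m=2, k=0)
            cicsp_accs.append(np.mean([cicsp.predict_mi(r, full) == l
                                       for r, l in test]))
            csp_accs.append(np.mean([cicsp.predict_mi(r, plain) == l
                                     for r, l in test]))
        assert np.mean(cicsp_accs) >= np.mean(csp_accs) - 0.01


class TestSerialization:
    def test_round_trip(self, mi_model, tmp_path):
        path = tmp_path / "model.npz"
        cicsp.save_model(mi_model, path)
        loaded = cicsp.load_model(path)
        np.testing.assert_array_equal(loaded.W, mi_model.W)
        np.testing.assert_array_equal(loaded.clf_w, mi_model.clf_w)
        assert loaded.classes == mi_model.classes
        assert loaded.m == mi_model.m and loaded.k == mi_model.k
        # loaded model decodes identically
        cfg = synth.SynthConfig(fs=FS, seed=8200)
        rec = synth.inject_mi_erd(synth.generate_background(cfg), "left", 0.8)
        assert cicsp.predict_mi_online(as_window(rec), loaded) == \
            cicsp.predict_mi_online(as_window(rec), mi_model)
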