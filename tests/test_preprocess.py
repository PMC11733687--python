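"""Cleaning: filters, z-value rejection, SOBI, spike components, ERP."""

import numpy as np
import pytest
from scipy import signal as sps

from speechrsa.preprocess import (
    DEFAULT_SOBI_LAGS,
    UnmixingModel,
    bandpass_epochs,
    detect_onset_spike_components,
    erp_average,
    joint_diagonalize,
    off_diagonal_energy,
    remove_components,
    sobi_unmix,
    zvalue_artifact_reject,
    zvalue_trial_scores,
)
from speechrsa.synthgen import (
    SynthConfig,
    generate_subject,
    inject_ci_artefact,
    make_ground_truth,
)

from conftest import make_epochs


class TestBandpass:
    def test_highpass_removes_dc(self, rng):
        data = np.full((3, 4, 2000), 7.5) + 0.01 * rng.standard_normal((3, 4, 2000))
        e = make_epochs(data, fs=500.0)
        out = bandpass_epochs(e, 0.1, 80.0)
        assert np.abs(out.data.mean()) < 0.05

    def test_notch_attenuates_line_noise_20db(self):
        fs = 500.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        e = make_epochs(np.tile(x, (2, 1, 1)), fs=fs)

        def power_at_50(data):
            freqs, pxx = sps.periodogram(data[0, 0], fs=fs)
            return pxx[np.argmin(np.abs(freqs - 50.0))]

        out = bandpass_epochs(e, 0.1, 120.0, notch=50.0)
        assert 10 * np.log10(power_at_50(e.data) / power_at_50(out.data)) >= 20.0

    def test_in_band_tone_amplitude_preserved(self):
        fs = 500.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        e = make_epochs(np.tile(x, (2, 1, 1)), fs=fs)
        out = bandpass_epochs(e, 0.1, 80.0)
        mid = slice(500, 2500)
        amp = np.abs(sps.hilbert(out.data[0, 0])[mid]).mean()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_invalid_corners_error(self, rng):
        e = make_epochs(rng.standard_normal((2, 2, 100)), fs=100.0)
        with pytest.raises(ValueError):
            bandpass_epochs(e, 30.0, 10.0)
        with pytest.raises(ValueError):
            bandpass_epochs(e, 0.1, 60.0)  # above Nyquist


class TestZValueRejection:
    def zscore_oracle(self, data):
        """Direct transcription of the score formula, independent code path."""
        n_tr, n_ch, n_s = data.shape
        scores = np.zeros(n_tr)
        for tr in range(n_tr):
            zsum = np.zeros(n_s)
            for ch in range(n_ch):
                mu = data[:, ch, :].mean()
                sd = data[:, ch, :].std()
                if sd > 0:
                    zsum += (data[tr, ch, :] - mu) / sd
            scores[tr] = (zsum / np.sqrt(n_ch)).max()
        return scores

    def test_identical_trials_no_rejection(self):
        data = np.tile(np.linspace(0, 1, 50), (4, 3, 1))
        e = make_epochs(data)
        out, report = zvalue_artifact_reject(e, 50.0)
        assert report.n_rejected == 0
        assert np.all(np.isfinite(report.scores))
        assert out.n_trials == 4

    def test_zero_variance_channel_warns_and_contributes_zero(self, rng):
        data = rng.standard_normal((5, 3, 40))
        data[:, 1, :] = 2.5  # dead channel
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = zvalue_trial_scores(data)
        assert np.all(np.isfinite(scores))
        # dead channel contributes z = 0: scores equal the oracle computed
        # on the live channels only (same sqrt(C) normalization)
        live = self.zscore_oracle(data[:, [0, 2], :]) * np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(scores, live, rtol=1e-10)

    def test_spike_trial_rejected_matches_oracle(self, rng):
        # 25 channels so a 50-SD spike on 10 channels clears threshold 50:
        # the expected score is recomputed with the independent oracle
        n_tr, n_ch, n_s = 20, 25, 100
        data = rng.standard_normal((n_tr, n_ch, n_s))
        data[7, :10, 42] += 50.0
        e = make_epochs(data)
        scores = zvalue_trial_scores(e.data)
        np.testing.assert_allclose(scores, self.zscore_oracle(e.data), rtol=1e-10)
        out, report = zvalue_artifact_reject(e, 50.0)
        np.testing.assert_array_equal(report.rejected, [7])
        assert out.n_trials == n_tr - 1

    def test_threshold_monotonicity(self, rng):
        data = rng.standard_normal((30, 8, 80))
        data[3, :, 10] += 40.0
        data[11, :, 20] += 80.0
        e = make_epochs(data)
        _, r50 = zvalue_artifact_reject(e, 5.0)
        _, r100 = zvalue_artifact_reject(e, 10.0)
        assert set(r100.rejected).issubset(set(r50.rejected))

    def test_trial_order_equivariance(self, rng):
        data = rng.standard_normal((10, 6, 50))
        perm = rng.permutation(10)
        s = zvalue_trial_scores(data)
        np.testing.assert_allclose(zvalue_trial_scores(data[perm]), s[perm])

    def test_single_trial_errors(self, rng):
        e = make_epochs(rng.standard_normal((1, 4, 50)))
        with pytest.raises(ValueError):
            zvalue_artifact_reject(e, 100.0)


class TestJointDiagonalization:
    def test_single_matrix_equals_eigendecomposition(self, rng):
        A = rng.standard_normal((6, 6))
        A = A + A.T
        V, rotated = joint_diagonalize(A[None])
        off = rotated[0] - np.diag(np.diag(rotated[0]))
        assert np.abs(off).max() < 1e-8
        # the recovered diagonal must be the eigenvalue spectrum
        np.testing.assert_allclose(
            np.sort(np.diag(rotated[0])), np.sort(np.linalg.eigvalsh(A)),
            rtol=1e-8,
        )

    def test_objective_not_increased(self, rng):
        mats = rng.standard_normal((5, 8, 8))
        mats = mats + mats.transpose(0, 2, 1)
        _, rotated = joint_diagonalize(mats)
        assert off_diagonal_energy(rotated) <= off_diagonal_energy(mats) + 1e-12

    def test_commuting_family_fully_diagonalized(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((7, 7)))
        mats = np.stack([Q @ np.diag(rng.standard_normal(7)) @ Q.T
                         for _ in range(4)])
        _, rotated = joint_diagonalize(mats)
        assert off_diagonal_energy(rotated) < 1e-12


class TestSOBI:
    def make_mixed_ar(self, rng, n_samples=6000, coeffs=(0.9, 0.2)):
        src = np.zeros((len(coeffs), n_samples))
        for k, a in enumerate(coeffs):
            e = rng.standard_normal(n_samples)
            for i in range(1, n_samples):
                src[k, i] = a * src[k, i - 1] + e[i]
        A = rng.standard_normal((len(coeffs), len(coeffs)))
        return src, A, A @ src

    def test_recovers_ar_sources_up_to_sign_permutation(self, rng):
        src, A, x = self.make_mixed_ar(rng)
        e = make_epochs(x.reshape(1, 2, -1), fs=500.0)
        model = sobi_unmix(e, lags=range(1, 21))
        est = model.unmixing @ x
        corr = np.corrcoef(np.vstack([src, est]))[:2, 2:]
        # best assignment: each true source matched by one estimate
        assert sorted(np.abs(corr).max(axis=1)) == pytest.approx([1.0, 1.0], abs=0.05)
        assert np.abs(np.abs(corr).max(axis=1)).min() >= 0.95

    def test_single_lag_matches_eigendecomposition(self, rng):
        # with one lag, joint diagonalization reduces to the
        # eigendecomposition of the whitened lagged covariance
        src, A, x = self.make_mixed_ar(rng, coeffs=(0.8, 0.3, -0.5))
        e = make_epochs(x.reshape(1, 3, -1), fs=500.0)
        model = sobi_unmix(e, lags=[2])
        data = e.data[0] - e.data[0].mean(axis=1, keepdims=True)
        C0 = data @ data.T / data.shape[1]
        evals, evecs = np.linalg.eigh(C0)
        W = evecs / np.sqrt(evals)
        Z = W.T @ data
        lag = 2
        Cl = Z[:, :-lag] @ Z[:, lag:].T / (Z.shape[1] - lag)
        Cl = 0.5 * (Cl + Cl.T)
        # rotated lagged covariance must be diagonal in the model basis
        V = model.unmixing @ np.linalg.pinv(W.T)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        rotated = V @ Cl @ V.T
        off = rotated - np.diag(np.diag(rotated))
        assert np.abs(off).max() < 1e-8

    def test_unmix_mix_round_trip(self, rng):
        x = rng.standard_normal((3, 8, 500))
        e = make_epochs(x, fs=500.0)
        model = sobi_unmix(e, lags=range(1, 6))
        ident = model.unmixing @ model.mixing
        np.testing.assert_allclose(ident, np.eye(model.n_components), atol=1e-6)
        recon = np.einsum("ck,tks->tcs", model.mixing, model.activations(e.data))
        assert np.abs(recon - e.data).max() / np.abs(e.data).max() < 1e-6

    def test_unit_norm_rows(self, rng):
        e = make_epochs(rng.standard_normal((2, 6, 400)), fs=500.0)
        model = sobi_unmix(e, lags=range(1, 6))
        np.testing.assert_allclose(
            np.linalg.norm(model.unmixing, axis=1), 1.0, rtol=1e-12
        )


class TestSpikeComponentDetection:
    def identity_model(self, n):
        return UnmixingModel(
            unmixing=np.eye(n), mixing=np.eye(n), lags=(1,),
            component_variances=np.ones(n), rank=n,
        )

    def epochs_with_component_time_courses(self, tcs):
        data = np.tile(np.asarray(tcs)[None], (3, 1, 1))
        return make_epochs(data, fs=500.0)

    def test_transient_component_flagged(self):
        times = np.arange(-1000.0, 1502.0, 2.0)
        quiet = 0.1 * np.sin(2 * np.pi * 3.0 * times / 1000.0)
        spike = quiet.copy()
        spike[np.abs(times) < 10] += 10.0 * 0.1
        e = self.epochs_with_component_time_courses([quiet, spike])
        flagged = detect_onset_spike_components(
            self.identity_model(2), e, ratio_threshold=5.0
        )
        assert flagged == [1]

    def test_exactly_at_threshold_not_flagged(self):
        times = np.arange(-1000.0, 1502.0, 2.0)
        base = np.ones_like(times)          # RMS outside windows = 1
        at_thr = base.copy()
        onset = np.argmin(np.abs(times))
        at_thr[onset] = 5.0                 # peak exactly 5 x RMS
        above = base.copy()
        above[onset] = 5.0 + 1e-6
        e = self.epochs_with_component_time_courses([at_thr, above])
        flagged = detect_onset_spike_components(
            self.identity_model(2), e, ratio_threshold=5.0
        )
        assert flagged == [1]

    def test_stationary_noise_rarely_flagged(self, rng):
        # null simulation: false-flag probability under stationary noise
        times = np.arange(-1000.0, 1502.0, 2.0)
        n_comp, n_sims, flags = 8, 10, 0
        for _ in range(n_sims):
            tcs = rng.standard_normal((n_comp, len(times)))
            e = self.epochs_with_component_time_courses(tcs)
            flags += len(
                detect_onset_spike_components(
                    self.identity_model(n_comp), e, ratio_threshold=5.0
                )
            )
        assert flags / (n_comp * n_sims) < 0.05


class TestRemoveComponents:
    def test_empty_set_is_identity(self, rng):
        e = make_epochs(rng.standard_normal((2, 6, 300)), fs=500.0)
        model = sobi_unmix(e, lags=range(1, 6))
        out = remove_components(e, model, [])
        np.testing.assert_allclose(out.data, e.data, atol=1e-10)

    def test_remove_all_zeroes_centred_data(self, rng):
        x = rng.standard_normal((2, 6, 300))
        x -= x.mean(axis=2, keepdims=True)
        e = make_epochs(x, fs=500.0)
        model = sobi_unmix(e, lags=range(1, 6))
        with pytest.warns(UserWarning):
            out = remove_components(e, model, range(model.n_components))
        assert np.abs(out.data).max() < 1e-8

    def test_metadata_and_shape_preserved(self, rng):
        e = make_epochs(rng.standard_normal((2, 6, 300)), fs=500.0,
                        subject="P01", group="implanted")
        model = sobi_unmix(e, lags=range(1, 6))
        out = remove_components(e, model, [0])
        assert out.data.shape == e.data.shape
        assert out.subject == "P01" and out.group == "implanted"
        assert out.trials.equals(e.trials)


class TestArtefactSuppressionEndToEnd:
    def test_sobi_removes_injected_implant_artefact(self):
        cfg = SynthConfig(
            n_subjects_per_group=1, n_channels=24, trials_per_condition=6,
            effect_scale=1.0, ears_implanted=("CI",), seed=11,
        )
        truth = make_ground_truth(cfg)
        clean = generate_subject(cfg, truth, "implanted", 0, "3m", "CI")
        dirty = inject_ci_artefact(clean, truth, amplitude=80.0)
        model = sobi_unmix(dirty, lags=DEFAULT_SOBI_LAGS)
        flagged = detect_onset_spike_components(model, dirty)
        assert flagged
        cleaned = remove_components(dirty, model, flagged)
        win = np.abs(dirty.times - 0.0) <= 20.0
        p_dirty = np.mean(dirty.data[:, :, win] ** 2)
        p_clean = np.mean(cleaned.data[:, :, win] ** 2)
        assert p_clean <= 0.10 * p_dirty


class TestERP:
    def test_identical_trials_average_to_one_trial(self, rng):
        trial = rng.standard_normal((4, 60))
        e = make_epochs(np.tile(trial, (5, 1, 1)), conditions=["x"] * 5)
        np.testing.assert_allclose(erp_average(e, "x"), trial)

    def test_average_is_count_weighted_linear(self, rng):
        data = rng.standard_normal((6, 3, 40))
        conds = ["a"] * 2 + ["b"] * 4
        e = make_epochs(data, conditions=conds)
        ea = erp_average(e.select_trials(np.array(conds) == "a"), "a")
        eb = erp_average(e.select_trials(np.array(conds) == "b"), "b")
        e_all = make_epochs(data, conditions=["all"] * 6)
        np.testing.assert_allclose(
            erp_average(e_all, "all"), (2 * ea + 4 * eb) / 6
        )

    def test_unknown_condition_errors(self, rng):
        e = make_epochs(rng.standard_normal((2, 2, 30)), conditions=["a", "a"])
        with pytest.raises(ValueError, match="unknown condition"):
            erp_average(e, "zzz")

    def test_injected_pattern_recovered(self):
        cfg = SynthConfig(
            n_subjects_per_group=1, n_channels=8, trials_per_condition=200,
            effect_scale=1.5, noise_white_sd=1.0, ears_implanted=("non-CI",),
            seed=3,
        )
        truth = make_ground_truth(cfg)
        e = generate_subject(cfg, truth, "control", 0, "reference", "earphone")
        cond = cfg.conditions[0]
        erp = erp_average(e, cond)
        inside = (e.times >= 600.0) & (e.times <= 1200.0)
        act = np.hanning(int(inside.sum()))
        expected = np.outer(truth.control_topographies[0], act)
        r = np.corrcoef(erp[:, inside].ravel(), expected.ravel())[0, 1]
        assert r >= 0.9
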