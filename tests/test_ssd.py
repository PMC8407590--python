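"""Spatio-spectral decomposition: filtering, covariances, GEVD, application."""

import numpy as np
import pytest
from scipy import linalg

import ssdkit as sk
from ssdkit.synth import SourceSpec
from tests.conftest import random_spd


def tone_recording(freq, fs=250.0, duration=30.0, weights=(1.0, 0.5, -0.5)):
    t = np.arange(0, duration, 1 / fs)
    src = np.sin(2 * np.pi * freq * t)
    return sk.Recording(data=np.outer(src, weights), fs=fs)


class TestBandpass:
    def test_passband_gain(self):
        rec = tone_recording(10.0)
        out = sk.bandpass_filter(rec, 8, 12)
        sl = slice(int(rec.fs), -int(rec.fs))
        ratio = out.data[sl, 0].std() / rec.data[sl, 0].std()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_stopband_attenuation(self):
        rec = tone_recording(25.0)
        out = sk.bandpass_filter(rec, 8, 12)
        sl = slice(int(rec.fs), -int(rec.fs))
        atten = 20 * np.log10(rec.data[sl, 0].std() / out.data[sl, 0].std())
        assert atten > 30

    def test_zero_in_zero_out(self):
        rec = sk.Recording(data=np.zeros((1000, 2)), fs=100.0)
        assert np.allclose(sk.bandpass_filter(rec, 8, 12).data, 0.0)

    def test_band_outside_nyquist_is_error(self):
        rec = tone_recording(10.0, fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            sk.bandpass_filter(rec, 8, 60)

    def test_short_recording_warns(self):
        rec = sk.Recording(
            data=np.random.default_rng(0).standard_normal((250, 2)), fs=250.0
        )
        with pytest.warns(UserWarning, match="settling"):
            sk.bandpass_filter(rec, 8, 12)


class TestBandCovariances:
    def test_duplicated_channel_rank_one(self, rng):
        x = rng.standard_normal(5000)
        rec = sk.Recording(data=np.column_stack([x, x]), fs=250.0)
        c_s, c_n = sk.band_covariances(rec, sk.make_band(10))
        assert np.linalg.matrix_rank(c_s, tol=1e-10 * np.abs(c_s).max()) == 1
        assert np.linalg.matrix_rank(c_n, tol=1e-10 * np.abs(c_n).max()) == 1

    def test_pure_tone_outer_product(self):
        weights = np.array([1.0, 0.5, -0.5])
        rec = tone_recording(10.0, fs=250.0, duration=60.0, weights=weights)
        c_s, c_n = sk.band_covariances(rec, sk.make_band(10))
        expected = np.outer(weights, weights) * 0.5  # tone variance = 1/2
        rel = np.linalg.norm(c_s - expected) / np.linalg.norm(expected)
        assert rel < 0.05
        assert np.abs(c_n).max() < 1e-3 * np.abs(c_s).max()

    def test_white_noise_trace_ratio_matches_bandwidths(self, rng):
        rec = sk.Recording(data=rng.standard_normal((120_000, 3)), fs=500.0)
        band = sk.make_band(10)
        c_s, c_n = sk.band_covariances(rec, band)
        sig_bw = band.signal_band[1] - band.signal_band[0]
        noise_bw = (band.flank_left[1] - band.flank_left[0]) + (
            band.flank_right[1] - band.flank_right[0]
        )
        assert np.trace(c_s) / np.trace(c_n) == pytest.approx(
            sig_bw / noise_bw, rel=0.2
        )


class TestSolveGevd:
    def test_identity_pair(self):
        w, lam, r = sk.solve_gevd(np.eye(3), np.eye(3))
        assert np.allclose(lam, 1.0) and r == 3

    def test_diagonal_analytic(self):
        w, lam, r = sk.solve_gevd(np.diag([4.0, 1.0]), np.eye(2))
        assert np.allclose(lam, [4.0, 1.0])
        assert abs(w[0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_rayleigh_oracle(self, rng):
        """Top eigenvalue dominates the Rayleigh quotient of 20k random
        directions, equals the top eigenvector's quotient, and matches an
        independent numerical maximization of the quotient."""
        from scipy.optimize import minimize

        for _ in range(5):
            k = int(rng.integers(2, 7))
            c_s, c_n = random_spd(rng, k), random_spd(rng, k)
            w, lam, r = sk.solve_gevd(c_s, c_n)
            v = rng.standard_normal((k, 20_000))
            quotients = np.einsum("ij,jk,ki->i", v.T, c_s, v) / np.einsum(
                "ij,jk,ki->i", v.T, c_n, v
            )
            assert lam[0] >= quotients.max() * (1 - 1e-12)
            top = w[:, 0]
            assert (top @ c_s @ top) / (top @ c_n @ top) == pytest.approx(
                lam[0], rel=1e-10
            )
            neg_q = lambda x: -(x @ c_s @ x) / (x @ c_n @ x)
            best = max(
                -minimize(neg_q, rng.standard_normal(k), method="BFGS").fun
                for _ in range(4)
            )
            assert best == pytest.approx(lam[0], rel=1e-6)

    def test_rank_deficient_expansion(self, rng):
        c_s = random_spd(rng, 4)
        # remove one principal direction from the signal covariance
        evals, evecs = linalg.eigh(c_s)
        evals[0] = 0.0
        c_s = evecs @ np.diag(evals) @ evecs.T
        c_n = random_spd(rng, 4)
        w, lam, r = sk.solve_gevd(0.5 * (c_s + c_s.T), c_n)
        assert r == 3 and w.shape == (4, 3)
        quot = np.einsum("ij,jk,ki->i", w.T, c_s, w) / np.einsum(
            "ij,jk,ki->i", w.T, c_n, w
        )
        assert np.allclose(quot, lam, rtol=1e-8)

    def test_rank_path_spans_direct_solution(self, rng):
        """Forcing the expansion path on full-rank input spans the same
        filter space as the direct path."""
        c_s, c_n = random_spd(rng, 5), random_spd(rng, 5)
        w_direct, lam_d, _ = sk.solve_gevd(c_s, c_n)
        w_exp, lam_e, _ = sk.solve_gevd(c_s, c_n, rank_tol=0.0)
        assert np.allclose(lam_d, lam_e, rtol=1e-8)
        # principal angles between the spans
        q1, _ = np.linalg.qr(w_direct)
        q2, _ = np.linalg.qr(w_exp)
        angles = np.arccos(np.clip(linalg.svdvals(q1.T @ q2), -1, 1))
        assert angles.max() < 1e-6

    def test_zero_noise_covariance_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            sk.solve_gevd(np.eye(3), np.zeros((3, 3)))

    def test_asymmetric_input_is_error(self, rng):
        c = random_spd(rng, 3)
        c[0, 1] += 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            sk.solve_gevd(c, np.eye(3))


class TestFitSsd:
    def test_rayleigh_identity_invariant(self, fitted_scene):
        rec, truth, model = fitted_scene
        assert np.allclose(
            model.rayleigh_quotients(), model.eigenvalues, rtol=1e-8
        )
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.n_components == model.rank

    def test_component_beats_every_electrode(self, fitted_scene):
        """The top filter's Rayleigh quotient dominates each canonical
        basis vector (single electrode) by construction."""
        rec, truth, model = fitted_scene
        for i in range(model.n_channels):
            e = np.zeros(model.n_channels)
            e[i] = 1.0
            q = (e @ model.c_signal @ e) / (e @ model.c_noise @ e)
            assert model.eigenvalues[0] > q

    def test_rank_deficient_recording(self, rng):
        base = rng.standard_normal((20_000, 3))
        mix = np.column_stack([np.eye(3), [1.0, 1.0, -1.0]])  # 4 ch, rank 3
        rec = sk.Recording(data=base @ mix, fs=250.0)
        model = sk.fit_ssd(rec, sk.make_band(10))
        assert model.rank == 3 and model.n_components == 3
        assert np.allclose(
            model.rayleigh_quotients(), model.eigenvalues, rtol=1e-8
        )

    def test_duplicated_channels_rank_one(self, rng):
        x = rng.standard_normal(20_000)
        rec = sk.Recording(data=np.column_stack([x, x]), fs=250.0)
        model = sk.fit_ssd(rec, sk.make_band(10))
        assert model.rank == 1 and model.n_components == 1

    def test_channel_scaling_invariance(self, rng):
        data = rng.standard_normal((30_000, 4))
        rec1 = sk.Recording(data=data, fs=250.0)
        scaled = data.copy()
        scaled[:, 2] *= 7.5
        rec2 = sk.Recording(data=scaled, fs=250.0)
        band = sk.make_band(10)
        s1 = sk.apply_filters(sk.fit_ssd(rec1, band), rec1)
        s2 = sk.apply_filters(sk.fit_ssd(rec2, band), rec2)
        for j in range(s1.shape[1]):
            scale = np.dot(s2[:, j], s1[:, j]) / np.dot(s1[:, j], s1[:, j])
            assert np.allclose(s2[:, j], scale * s1[:, j], atol=1e-8 * np.abs(s1[:, j]).max())

    def test_mne_ssd_cross_check(self):
        """Independent implementation check: the top spatial filter agrees
        with mne.decoding.SSD on a strong single-source mixture."""
        mne = pytest.importorskip("mne")
        from mne.decoding import SSD

        rng = np.random.default_rng(7)
        fs = 250.0
        t = np.arange(0, 120, 1 / fs)
        src = np.sin(2 * np.pi * 10 * t) * (1 + 0.3 * np.sin(2 * np.pi * 0.2 * t))
        mix = np.array([1.0, 0.6, -0.4, 0.2, 0.1])
        data = np.outer(src, mix) + 0.6 * rng.standard_normal((t.size, 5))
        rec = sk.Recording(data=data, fs=fs)
        model = sk.fit_ssd(rec, sk.make_band(10))

        info = mne.create_info([f"e{i}" for i in range(5)], fs, "eeg")
        ssd = SSD(
            info,
            filt_params_signal=dict(l_freq=8, h_freq=12,
                                    l_trans_bandwidth=1, h_trans_bandwidth=1),
            filt_params_noise=dict(l_freq=6, h_freq=14,
                                   l_trans_bandwidth=1, h_trans_bandwidth=1),
            reg=None, rank="full",
        )
        ssd.fit(data.T)
        w_mne = ssd.filters_[0, :]  # mne stores filters as rows
        w_ours = model.filters[:, 0]
        cos = abs(w_mne @ w_ours) / (
            np.linalg.norm(w_mne) * np.linalg.norm(w_ours)
        )
        assert cos > 0.95


class TestApplyFilters:
    def test_identity_filters(self, rng):
        rec = sk.Recording(data=rng.standard_normal((5000, 3)), fs=250.0)
        model = sk.fit_ssd(rec, sk.make_band(10))
        ident = sk.SSDModel(
            filters=np.eye(3), eigenvalues=np.ones(3), band=model.band,
            c_signal=np.eye(3), c_noise=np.eye(3), rank=3,
        )
        assert np.array_equal(sk.apply_filters(ident, rec), rec.data)

    def test_harmonic_preserved_from_broadband(self):
        """A non-sinusoidal source's harmonic survives spatial filtering of
        the broadband data at least as well as on the best electrode."""
        specs = [SourceSpec(kind="arc", freq=10.0, amplitude=1.5,
                            asymmetry=0.35, location=(30.0, 30.0, 0.0),
                            spatial_scale=20.0)]
        rec, truth = sk.simulate_recording(
            specs, duration=90.0, fs=500.0, seed=3, n_channels=6,
            noise_amp=0.3,
        )
        model = sk.fit_ssd(rec, sk.make_band(10))
        comp = sk.apply_filters(model, rec, 1)
        harm_band = (18.0, 22.0)
        comp_snr = sk.band_snr_db(
            sk.fit_spectrum(sk.compute_psd(comp, fs=rec.fs)), harm_band
        )
        elec_snrs = [
            sk.band_snr_db(f, harm_band)
            for f in sk.fit_channels(sk.compute_psd(rec))
        ]
        assert comp_snr >= max(elec_snrs) - 1e-9

    def test_zero_components_empty(self, fitted_scene):
        rec, truth, model = fitted_scene
        out = sk.apply_filters(model, rec, 0)
        assert out.shape == (rec.n_samples, 0)

    def test_channel_mismatch_is_error(self, fitted_scene, rng):
        rec, truth, model = fitted_scene
        other = sk.Recording(data=rng.standard_normal((1000, 3)), fs=1000.0)
        with pytest.raises(ValueError, match="channels"):
            sk.apply_filters(model, other)


class TestModelSerialization:
    def test_json_roundtrip(self, fitted_scene, tmp_path):
        rec, truth, model = fitted_scene
        path = str(tmp_path / "model.json")
        model.to_json(path)
        back = sk.SSDModel.from_json(path)
        assert np.array_equal(back.filters, model.filters)
        assert np.array_equal(back.eigenvalues, model.eigenvalues)
        assert back.band == model.band and back.rank == model.rank
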