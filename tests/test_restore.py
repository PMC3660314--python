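"""Deconvolution, unmixing, and artifact-score tests."""

import numpy as np
import pytest

from qdti import (
    Band,
    DeconvParams,
    OpticalConfig,
    cmle_deconvolve,
    linear_unmix,
    make_nexciton_psf,
    periodicity_score,
)
from qdti.acquisition import ImageStack, SpectralStack
from qdti.optics_psf import PSF, psf_fwhm
from qdti.photophysics import FLUOROPHORES, emission_spectrum
from qdti.restore import estimate_background, unmix_single_check


def _stack(values):
    return ImageStack(np.asarray(values, float), 50.0, 50.0, 150.0)


def _delta_psf(shape=(5, 5, 5)):
    v = np.zeros(shape)
    v[tuple(s // 2 for s in shape)] = 1.0
    return PSF(v, 50.0, 50.0, 150.0)


def _gauss_psf(shape=(9, 33, 33), sigma_vox=2.0):
    z, y, x = [np.arange(s) - s // 2 for s in shape]
    v = np.exp(-0.5 * ((z[:, None, None] / sigma_vox) ** 2
                       + (y[None, :, None] / sigma_vox) ** 2
                       + (x[None, None, :] / sigma_vox) ** 2))
    return PSF(v / v.sum(), 50.0, 50.0, 150.0)


class TestCMLE:
    def test_delta_psf_is_identity(self, rng):
        img = _stack(rng.random((7, 16, 16)) * 100.0)
        out = cmle_deconvolve(img, _delta_psf(),
                              DeconvParams(iterations=5, background=0.0))
        np.testing.assert_allclose(out.values, img.values, atol=1e-9)

    def test_blurred_point_sharpens(self):
        psf = _gauss_psf()
        point = np.zeros((9, 33, 33))
        point[4, 16, 16] = 1000.0
        from qdti.acquisition import _convolve_reflect

        blurred = _stack(_convolve_reflect(point, psf.values))
        out = cmle_deconvolve(blurred, psf,
                              DeconvParams(iterations=40, background=0.0))
        f_in = psf_fwhm(PSF(blurred.values, 50.0, 50.0, 150.0), "x")
        f_out = psf_fwhm(PSF(out.values, 50.0, 50.0, 150.0), "x")
        assert f_out < f_in

    def test_flux_conserved_and_nonnegative_each_iteration(self, rng):
        """With zero background the RL update conserves total intensity and
        non-negativity at every iteration."""
        psf = _gauss_psf(shape=(5, 17, 17), sigma_vox=1.5)
        img = _stack(rng.poisson(50.0, (5, 24, 24)).astype(float))
        total0 = img.values.sum()
        for iters in (1, 2, 5, 10):
            out = cmle_deconvolve(img, psf,
                                  DeconvParams(iterations=iters, background=0.0))
            assert np.all(out.values >= 0)
            assert out.values.sum() == pytest.approx(total0, rel=1e-6)

    def test_fwhm_decreases_monotonically_over_iterations(self):
        """Filament width shrinks monotonically through the first 40 RL
        iterations on noiseless blurred data."""
        psf = _gauss_psf(shape=(5, 33, 33), sigma_vox=2.0)
        line = np.zeros((5, 33, 33))
        line[2, :, 16] = 100.0
        from qdti.acquisition import _convolve_reflect

        blurred = _stack(_convolve_reflect(line, psf.values))
        widths = []
        for iters in (5, 10, 20, 40):
            out = cmle_deconvolve(blurred, psf,
                                  DeconvParams(iterations=iters, background=0.0))
            prof = out.values[2, 16, :]
            from qdti.optics_psf import profile_fwhm

            widths.append(profile_fwhm(np.arange(33) * 50.0, prof))
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    def test_grid_mismatch_rejected(self, rng):
        img = _stack(rng.random((5, 8, 8)))
        psf = PSF(np.ones((3, 3, 3)) / 27.0, 40.0, 40.0, 150.0)
        with pytest.raises(ValueError, match="voxel"):
            cmle_deconvolve(img, psf)

    def test_all_zero_image_warns_and_returns_zeros(self):
        img = _stack(np.zeros((5, 8, 8)))
        with pytest.warns(UserWarning):
            out = cmle_deconvolve(img, _delta_psf(), DeconvParams(iterations=2))
        assert not np.any(out.values)

    def test_background_estimate_is_histogram_mode(self, rng):
        vals = np.concatenate([rng.normal(10.0, 0.5, 5000),
                               rng.normal(200.0, 5.0, 100)])
        assert estimate_background(vals) == pytest.approx(10.0, abs=1.0)


def _make_spectral(abund_maps, refs, edges, noise_rng=None):
    """Forward-model a spectral stack from known abundances."""
    n_bands = len(edges) - 1
    shape = abund_maps[0].shape
    values = np.zeros((n_bands,) + shape)
    from qdti.photophysics import band_flux

    for amap, ref in zip(abund_maps, refs):
        sig = np.array([band_flux(ref, Band(edges[i], edges[i + 1]))
                        for i in range(n_bands)])
        sig = sig / np.linalg.norm(sig)
        values += sig[:, None, None, None] * amap[None]
    if noise_rng is not None:
        values = noise_rng.poisson(np.clip(values, 0, None)).astype(float)
    return SpectralStack(values, np.asarray(edges, float), 50.0, 50.0, 150.0)


def _dapi_qd_refs():
    return [emission_spectrum(FLUOROPHORES["DAPI"].emission, 5.0),
            emission_spectrum(FLUOROPHORES["QD655"].emission, 5.0)]


class TestLinearUnmix:
    EDGES = np.arange(430.0, 611.0, 10.0)

    def test_noiseless_recovery_exact(self, rng):
        refs = _dapi_qd_refs()
        a1 = rng.random((3, 8, 8)) * 100.0
        a2 = rng.random((3, 8, 8)) * 100.0
        stack = _make_spectral([a1, a2], refs, self.EDGES)
        abund, resid = linear_unmix(stack, refs)
        np.testing.assert_allclose(abund[0], a1, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(abund[1], a2, rtol=1e-6, atol=1e-8)
        assert resid.max() < 1e-6 * max(a1.max(), a2.max())

    def test_single_reference_projection(self, rng):
        refs = _dapi_qd_refs()[1:]
        a = rng.random((2, 6, 6)) * 50.0
        stack = _make_spectral([a], refs, self.EDGES)
        coef, resid = unmix_single_check(stack, refs[0])
        np.testing.assert_allclose(coef, a, rtol=1e-9)
        assert resid.max() < 1e-9 * a.max()

    def test_poisson_noisy_recovery_within_10_percent(self, rng):
        """Monte-Carlo check at ~100 peak counts per voxel per scan."""
        refs = _dapi_qd_refs()
        shape = (2, 12, 12)
        a1 = np.full(shape, 150.0)
        a2 = np.full(shape, 250.0)
        stack = _make_spectral([a1, a2], refs, self.EDGES, noise_rng=rng)
        abund, _ = linear_unmix(stack, refs)
        err1 = np.median(np.abs(abund[0] - a1) / a1)
        err2 = np.median(np.abs(abund[1] - a2) / a2)
        assert err1 < 0.10 and err2 < 0.10

    def test_collinear_references_named(self):
        refs = [_dapi_qd_refs()[0]] * 2
        stack = _make_spectral([np.ones((1, 4, 4))], refs[:1], self.EDGES)
        with pytest.raises(ValueError, match="0 and 1"):
            linear_unmix(stack, refs)

    def test_fewer_than_two_references_rejected(self):
        refs = _dapi_qd_refs()
        stack = _make_spectral([np.ones((1, 4, 4))], refs[:1], self.EDGES)
        with pytest.raises(ValueError, match="at least 2"):
            linear_unmix(stack, refs[:1])


class TestPeriodicityScore:
    def test_white_noise_scores_low(self, rng):
        img = rng.normal(100.0, 10.0, (4, 64, 64))
        mask = np.ones_like(img, dtype=bool)
        assert periodicity_score(img, mask) < 3.0

    def test_planted_sinusoid_detected(self, rng):
        noise = rng.normal(100.0, 10.0, (4, 64, 64))
        x = np.arange(64)
        pattern = 10.0 * np.sin(2 * np.pi * x / 8.0)  # 10% of the mean
        img = noise + pattern[None, None, :]
        mask = np.ones_like(img, dtype=bool)
        base = periodicity_score(noise, mask)
        assert periodicity_score(img, mask) >= 5.0 * base

    def test_scale_invariance(self, rng):
        img = rng.normal(100.0, 10.0, (2, 32, 32))
        mask = np.ones_like(img, dtype=bool)
        s1 = periodicity_score(img, mask)
        s2 = periodicity_score(img * 1e4, mask)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_tiny_mask_rejected(self, rng):
        img = rng.normal(0.0, 1.0, (2, 32, 32))
        mask = np.zeros_like(img, dtype=bool)
        mask[0, :3, :3] = True
        with pytest.raises(ValueError, match="10%"):
            periodicity_score(img, mask)

    def test_comparison_harness_2p_vs_3p(self):
        """Both deconvolution PSF models run under identical settings and
        their backgrounds are comparable via the score (the published
        workflow chose the 2-photon model after such a comparison)."""
        rng = np.random.default_rng(5)
        from qdti.phantoms import make_filaments
        from qdti.acquisition import render_channel, ChannelConfig, DetectorModel

        ph = make_filaments(2, seed=5, shape=(9, 64, 64))
        opt = OpticalConfig(dx=50.0, dy=50.0, dz=150.0)
        ch = ChannelConfig("QD655", 405.0, 5.0, Band(580.0, 610.0), opt, 3)
        det = DetectorModel()
        img = render_channel(ph, ch, det, seed=5, photon_scale=1e-4)
        scores = {}
        for order in (2, 3):
            from dataclasses import replace

            cfg = replace(opt, lambda_exc=405.0, lambda_em=595.0,
                          photon_order=order)
            psf = make_nexciton_psf(cfg, shape=(9, 33, 33))
            out = cmle_deconvolve(img, psf, DeconvParams(iterations=20))
            mask = ph.density["QD655"] < 1e-6
            scores[order] = periodicity_score(out, mask)
        assert set(scores) == {2, 3}
        assert all(np.isfinite(v) for v in scores.values())
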