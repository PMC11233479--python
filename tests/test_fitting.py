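"""Dictionary T2 fitting: atom recovery, noise behaviour, synthesis."""

import numpy as np
import pytest

from ktmese.epg import (
    build_dictionary,
    default_t2_grid,
    epg_echo_train,
    saturation_factor,
)
from ktmese.fitting import T2MapResult, estimate_noise_sigma, fit_t2_epg, synthesize_t2w
from ktmese.recon import EchoImageSeries


def _series(images, prot):
    return EchoImageSeries(np.asarray(images, complex),
                           np.asarray(prot.echo_times_ms))


class TestAtomRecovery:
    def test_exact_atom_recovered_with_scale(self, bh_prot, bh_dictionary):
        d = bh_dictionary
        i = 700
        sig = d.atoms[i] * d.norms[i] * 3.7
        imgs = np.zeros((4, 4, bh_prot.n_echoes))
        imgs[1, 1] = sig
        res = fit_t2_epg(_series(imgs, bh_prot), d, noise_floor=1e-9,
                         rician_correction=False)
        assert res.t2_ms[1, 1] == d.t2_ms[i]
        assert res.b1_scale[1, 1] == d.b1[i]
        assert res.amplitude[1, 1] == pytest.approx(3.7, abs=1e-10)
        assert res.residual[1, 1] <= 1e-10

    def test_all_zero_pixel_marked_invalid(self, bh_prot, bh_dictionary):
        imgs = np.zeros((4, 4, bh_prot.n_echoes))
        imgs[0, 0, :] = 1.0
        res = fit_t2_epg(_series(imgs, bh_prot), bh_dictionary, noise_floor=0.0)
        assert res.valid[0, 0]
        assert not res.valid[2, 2]
        assert res.t2_ms[2, 2] < 0  # sentinel

    def test_echo_count_mismatch_rejected(self, bh_prot, bh_dictionary):
        imgs = np.zeros((4, 4, bh_prot.n_echoes + 1))
        te = np.arange(bh_prot.n_echoes + 1) * 13.0
        with pytest.raises(ValueError):
            fit_t2_epg(EchoImageSeries(imgs.astype(complex), te), bh_dictionary)

    def test_matching_equals_brute_force_on_crop(self, bh_prot, bh_dictionary,
                                                 rng):
        """Vectorised argmax equals exhaustive residual minimisation."""
        d = bh_dictionary
        n = 16 * 16
        t2 = rng.uniform(40, 400, n)
        trains = np.abs(
            epg_echo_train(t2, np.full(n, 1500.0), bh_prot.esp_ms,
                           bh_prot.refoc_schedule_deg, 1.0)
        ).T
        noisy = trains + rng.normal(0, 0.01, trains.shape)
        imgs = noisy.reshape(16, 16, bh_prot.n_echoes)
        res = fit_t2_epg(_series(imgs, bh_prot), d, noise_floor=1e-9,
                         rician_correction=False)
        X = np.abs(imgs.reshape(-1, bh_prot.n_echoes))
        # oracle: minimise ||x − a·atom|| over atoms at the optimal scale
        scal = X @ d.atoms.T
        resid = np.linalg.norm(X, axis=1, keepdims=True) ** 2 - scal**2
        oracle = np.argmin(resid, axis=1)
        np.testing.assert_array_equal(res.t2_ms.ravel(), d.t2_ms[oracle])

    def test_noiseless_bias_bounded_by_grid_spacing(self, bh_prot):
        d = build_dictionary(default_t2_grid(), [1.0], 1500.0, bh_prot)
        t2_true = np.array([55.0, 97.0, 143.0, 210.0])
        trains = np.abs(
            epg_echo_train(t2_true, np.full(4, 1500.0), bh_prot.esp_ms,
                           bh_prot.refoc_schedule_deg, 1.0)
        ).T * saturation_factor(bh_prot.tr_ms, 1500.0, bh_prot.te_max_ms)
        imgs = trains.reshape(1, 4, bh_prot.n_echoes)
        res = fit_t2_epg(_series(imgs, bh_prot), d, noise_floor=1e-9,
                         rician_correction=False)
        # log-grid spacing ≈ 2.34%: recovered values within one grid step
        step = np.log(3000 / 30) / 199
        assert np.all(
            np.abs(np.log(res.t2_ms[0] / t2_true)) <= step / 2 + 1e-12
        )


class TestNoiseRecovery:
    def test_snr30_median_error_within_two_percent(self, hr_prot, rng):
        """Rician-magnitude recovery at SNR 30 over T2 ∈ [50, 250] ms.

        Simulated at nominal transmit (B1 = 1, matching the phantom
        simulator), fitted with the default T2 grid.
        """
        d = build_dictionary(default_t2_grid(), [1.0], 1500.0, hr_prot)
        n = 2304
        t2_true = rng.uniform(50, 250, n)
        trains = np.abs(
            epg_echo_train(t2_true, np.full(n, 1500.0), hr_prot.esp_ms,
                           hr_prot.refoc_schedule_deg, 1.0)
        ).T
        sigma = trains[:, 0].mean() / 30.0
        ne = hr_prot.n_echoes
        noisy = np.abs(
            trains
            + rng.normal(0, sigma / np.sqrt(2), (n, ne))
            + 1j * rng.normal(0, sigma / np.sqrt(2), (n, ne))
        )
        imgs = np.zeros((80, 80, ne))
        body = np.zeros((80, 80), dtype=bool)
        body[16:64, 16:64] = True
        imgs[body] = noisy
        noise_bg = np.abs(
            rng.normal(0, sigma / np.sqrt(2), (80, 80, ne))
            + 1j * rng.normal(0, sigma / np.sqrt(2), (80, 80, ne))
        )
        imgs[~body] = noise_bg[~body]
        res = fit_t2_epg(_series(imgs, hr_prot), d)
        fitted = res.t2_ms[body]
        assert res.valid[body].all()
        err = np.abs(fitted - t2_true) / t2_true
        assert np.median(err) <= 0.02

    def test_noise_sigma_estimate_from_corners(self, rng):
        sigma = 0.05
        img = rng.normal(0, sigma / np.sqrt(2), (64, 64)) + 1j * rng.normal(
            0, sigma / np.sqrt(2), (64, 64)
        )
        est = estimate_noise_sigma(img)
        assert est == pytest.approx(sigma / np.sqrt(2), rel=0.25)


class TestSynthesis:
    def _map(self, t2, amp=1.0, valid=True):
        shape = np.shape(t2)
        return T2MapResult(
            t2_ms=np.asarray(t2, float),
            amplitude=np.full(shape, amp),
            b1_scale=np.ones(shape),
            residual=np.zeros(shape),
            valid=np.full(shape, valid),
        )

    def test_closed_form_value(self):
        img = synthesize_t2w(self._map([[100.0]]), 100.0)
        assert img[0, 0] == pytest.approx(0.3679, abs=1e-4)

    def test_zero_te_returns_amplitude_map(self):
        m = self._map([[50.0, 200.0]], amp=2.5)
        np.testing.assert_allclose(synthesize_t2w(m, 0.0), 2.5)

    def test_long_t2_is_brighter(self):
        m = self._map([[50.0, 200.0]])
        img = synthesize_t2w(m, 100.0)
        assert img[0, 1] > img[0, 0]
        np.testing.assert_allclose(img[0], [0.1353, 0.6065], atol=1e-4)

    def test_invalid_pixels_are_zero_and_negative_te_rejected(self):
        m = self._map([[100.0]], valid=False)
        assert synthesize_t2w(m, 50.0)[0, 0] == 0.0
        with pytest.raises(ValueError):
            synthesize_t2w(m, -1.0)
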