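"""EPG signal model: closed-form limits, isochromat oracle, dictionaries."""

import math

import numpy as np
import pytest

from ktmese.epg import (
    build_dictionary,
    default_t2_grid,
    epg_echo_train,
    epg_mese_signal,
)
from ktmese.isochromat import isochromat_mese_signal
from ktmese.protocols import AcquisitionProtocol, reduced_flip_schedule


class TestCpmgLimit:
    """With ideal 180° refocusing and T1 → ∞ the train is exp(−TE/T2)."""

    def test_three_echo_example(self, cpmg_prot):
        sig = epg_mese_signal(100.0, 1e9, cpmg_prot)
        np.testing.assert_allclose(
            sig.amplitudes, [0.9048, 0.8187, 0.7408], atol=5e-5
        )

    @pytest.mark.parametrize("t2", [20.0, 50.0, 150.0, 600.0, 2000.0])
    def test_exponential_over_t2_range(self, t2):
        prot = AcquisitionProtocol(
            name="cpmg30", esp_ms=7.8, n_echoes=30, tr_ms=math.inf,
            refoc_schedule_deg=tuple([180.0] * 30), matrix=(64, 64),
        )
        sig = epg_mese_signal(t2, 1e9, prot)
        expected = np.exp(-np.asarray(prot.echo_times_ms) / t2)
        assert np.max(np.abs(sig.amplitudes - expected) / expected) < 1e-6

    def test_cpmg_amplitudes_strictly_decrease(self, cpmg_prot):
        sig = epg_mese_signal(80.0, 1e9, cpmg_prot)
        assert np.all(np.diff(sig.amplitudes) < 0)


class TestIsochromatOracle:
    """EPG must agree with brute-force spin-ensemble summation."""

    def test_reduced_flip_schedule(self, hr_prot):
        epg = epg_mese_signal(100.0, 1500.0, hr_prot).amplitudes
        # TR is effectively infinite for this protocol, so no saturation scale
        iso = isochromat_mese_signal(
            100.0, 1500.0, hr_prot.esp_ms, hr_prot.refoc_schedule_deg,
            n_spins=2000,
        )
        assert np.max(np.abs(epg - iso)) <= 1e-3

    @pytest.mark.parametrize("angle", [60.0, 90.0, 120.0, 150.0, 180.0])
    def test_constant_schedules(self, angle):
        schedule = [angle] * 12
        epg = np.abs(epg_echo_train(80.0, 1200.0, 9.0, schedule))[:, 0]
        iso = isochromat_mese_signal(80.0, 1200.0, 9.0, schedule, n_spins=2000)
        assert np.max(np.abs(epg - iso)) <= 1e-3

    def test_b1_scaling_matches_oracle(self, hr_prot):
        epg = np.abs(
            epg_echo_train(120.0, 1500.0, hr_prot.esp_ms,
                           hr_prot.refoc_schedule_deg, 0.85)
        )[:, 0]
        iso = isochromat_mese_signal(
            120.0, 1500.0, hr_prot.esp_ms, hr_prot.refoc_schedule_deg,
            b1_scale=0.85, n_spins=2000,
        )
        assert np.max(np.abs(epg - iso)) <= 1e-3


class TestEpgProperties:
    def test_zero_b1_gives_zero_echoes(self):
        train = np.abs(epg_echo_train(100.0, 1500.0, 10.0, [110.0] * 6, 0.0))
        assert np.max(train) < 1e-12

    def test_truncation_invariance(self, hr_prot):
        full = epg_echo_train(
            80.0, 1500.0, hr_prot.esp_ms, hr_prot.refoc_schedule_deg,
            n_states=hr_prot.n_echoes + 1,
        )
        more = epg_echo_train(
            80.0, 1500.0, hr_prot.esp_ms, hr_prot.refoc_schedule_deg,
            n_states=4 * hr_prot.n_echoes,
        )
        np.testing.assert_allclose(full, more, atol=1e-14)

    def test_stimulated_echoes_raise_late_signal(self, hr_prot):
        """Reduced flips redistribute signal: the apparent decay is slower
        than mono-exponential at matched T2."""
        sig = epg_mese_signal(100.0, 1500.0, hr_prot).amplitudes
        mono = np.exp(-np.asarray(hr_prot.echo_times_ms) / 100.0)
        assert sig[-1] > mono[-1]

    def test_invalid_inputs_raise(self, hr_prot):
        with pytest.raises(ValueError):
            epg_mese_signal(-5.0, 1500.0, hr_prot)
        with pytest.raises(ValueError):
            epg_mese_signal(100.0, 1500.0, hr_prot, b1_scale=1.5)
        with pytest.raises(ValueError):
            epg_echo_train(100.0, 50.0, 10.0, [180.0] * 3)  # T1 < T2


class TestDictionary:
    def test_atom_count_and_normalisation(self, cpmg_prot):
        d = build_dictionary([50.0, 100.0], [1.0], 1500.0, cpmg_prot)
        assert len(d) == 2
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=1), 1.0,
                                   atol=1e-12)

    def test_atom_matches_signal_definition(self, bh_prot):
        d = build_dictionary([100.0], [1.0], 1500.0, bh_prot)
        sig = epg_mese_signal(100.0, 1500.0, bh_prot).amplitudes
        np.testing.assert_allclose(d.atoms[0], sig / np.linalg.norm(sig),
                                   atol=1e-12)
        np.testing.assert_allclose(d.norms[0], np.linalg.norm(sig), atol=1e-12)

    def test_off_grid_match_is_residual_minimiser(self, bh_prot):
        d = build_dictionary(default_t2_grid(), [1.0], 1500.0, bh_prot)
        target = epg_mese_signal(97.0, 1500.0, bh_prot).amplitudes
        # brute force: residual of the optimally scaled atom, all atoms
        scale = d.atoms @ target
        resid = np.linalg.norm(target) ** 2 - scale**2
        best = int(np.argmin(resid))
        # exhaustive check against the nearest grid points
        grid_best = int(np.argmin(np.abs(d.t2_ms - 97.0)))
        assert best == grid_best

    def test_empty_grid_rejected(self, bh_prot):
        with pytest.raises(ValueError):
            build_dictionary([], [1.0], 1500.0, bh_prot)
        with pytest.raises(ValueError):
            build_dictionary([100.0, 50.0], [1.0], 1500.0, bh_prot)


class TestProtocolSerialisation:
    def test_yaml_round_trip(self, tmp_path, hr_prot):
        p = tmp_path / "prot.yaml"
        hr_prot.to_yaml(p)
        back = type(hr_prot).from_yaml(p)
        assert back.esp_ms == hr_prot.esp_ms
        assert back.n_echoes == hr_prot.n_echoes
        assert back.refoc_schedule_deg == hr_prot.refoc_schedule_deg
        assert math.isinf(back.tr_ms)

    def test_schedule_expansion(self):
        assert reduced_flip_schedule(5) == [175.0, 145.0, 110.0, 110.0, 110.0]

    def test_echo_counts_from_te_ranges(self, hr_prot, bh_prot):
        # 234/7.8 and 182/13 echoes with TE[k] = (k+1)·ESP
        assert hr_prot.n_echoes == 30 and hr_prot.te_max_ms == pytest.approx(234.0)
        assert bh_prot.n_echoes == 14 and bh_prot.te_max_ms == pytest.approx(182.0)
        assert hr_prot.echo_times_ms[0] == pytest.approx(7.8)

    def test_schedule_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(
                name="bad", esp_ms=10.0, n_echoes=4, tr_ms=1000.0,
                refoc_schedule_deg=(180.0,), matrix=(64, 64),
            )
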