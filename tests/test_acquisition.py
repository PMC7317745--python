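"""Signal synthesis: b-values, the closed-form forward model, and the
DEXSY/DOSY/FEXSY cosine-mean synthesis from walks."""

import numpy as np
import pytest

from dexsy.acquisition import (GAMMA_H, DexsySequence, PgsePair, b_value,
                               dexsy_waveforms, forward_signal,
                               forward_signal_1d, pair_waveform,
                               read_signal_matrix, synthesize_dexsy,
                               synthesize_dosy, synthesize_fexsy,
                               write_signal_matrix)
from dexsy.montecarlo import WalkParams

D0 = 2.0e-9


class TestBValue:
    def test_zero_gradient(self):
        assert b_value(0.0, 15e-3, 17e-3) == 0.0

    def test_quadratic_in_G(self):
        assert b_value(0.2, 15e-3, 17e-3) == pytest.approx(
            4 * b_value(0.1, 15e-3, 17e-3))

    def test_in_vitro_maximum_gradient(self):
        # independent hand evaluation of gamma^2 d^2 G^2 (D - d/3):
        # (2.675e8)^2 * 0.015^2 * 0.64^2 * (0.017 - 0.005) = 7.9131e10
        assert b_value(0.64, 15e-3, 17e-3) == pytest.approx(7.9131e10,
                                                            rel=1e-4)

    def test_delta_exceeding_Delta_rejected(self):
        with pytest.raises(ValueError):
            b_value(0.1, 18e-3, 17e-3)


class TestForwardSignal:
    def test_single_component_zero_b(self):
        S = forward_signal([[1.0]], [1e-9], [1e-9], [0.0], [0.0])
        assert S[0, 0] == pytest.approx(1.0)

    def test_single_component_closed_form(self):
        b1, b2 = np.array([0.0, 2e9]), np.array([0.0, 5e8])
        S = forward_signal([[1.0]], [1e-9], [1e-9], b1, b2)
        expected = np.exp(-(b1[:, None] + b2[None, :]) * 1e-9)
        np.testing.assert_allclose(S, expected)

    def test_four_components_match_term_by_term_sum(self):
        D = np.array([1e-10, 1e-9])
        W = np.array([[0.5, 0.1], [0.1, 0.3]])
        b1 = np.linspace(0, 3e9, 5)
        b2 = np.linspace(0, 1e9, 4)
        S = forward_signal(W, D, D, b1, b2)
        # brute-force oracle: explicit loop over the four components
        expected = np.zeros((5, 4))
        for k in range(2):
            for l in range(2):
                expected += W[k, l] * np.exp(-np.outer(b1, [D[k]])) \
                    * np.exp(-np.outer(b2, [D[l]])).T[0]
        np.testing.assert_allclose(S, expected, rtol=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            forward_signal([[-0.1]], [1e-9], [1e-9], [0.0], [0.0])
        with pytest.raises(ValueError):
            forward_signal_1d([-1.0], [1e-9], [0.0])


class TestWaveforms:
    def test_pair_waveform_layout_and_rounding(self):
        w, d_r, D_r = pair_waveform(1000, 1e-4, 0.0, 15e-3, 17e-3)
        assert d_r == pytest.approx(15e-3)
        assert D_r == pytest.approx(17e-3)
        assert np.all(w[:150] == 1.0)
        assert np.all(w[150:170] == 0.0)
        assert np.all(w[170:320] == -1.0)
        assert np.all(w[320:] == 0.0)

    def test_sequence_longer_than_simulation_rejected(self):
        seq = DexsySequence()
        with pytest.raises(ValueError, match="steps"):
            dexsy_waveforms(seq, 1000, 2.5e-5)

    def test_sequence_validation(self):
        with pytest.raises(ValueError):
            DexsySequence(tm=-0.1)
        with pytest.raises(ValueError):
            DexsySequence(G1=np.array([0.1, 0.2]))  # missing S0 cell
        with pytest.raises(ValueError):
            PgsePair(G=0.1, delta=2e-2, Delta=1e-2)


class TestFreeDiffusionSynthesis:
    @pytest.fixture(scope="class")
    def free_dexsy(self):
        seq = DexsySequence(G1=np.linspace(0, 0.3, 6),
                            G2=np.linspace(0, 0.3, 6))
        params = WalkParams(n_walkers=20_000, duration=0.17, n_steps=6800,
                            seed=21)
        return synthesize_dexsy(None, seq, substrate=None, params=params)

    def test_s0_cell_is_one(self, free_dexsy):
        assert free_dexsy.values[0, 0] == 1.0

    def test_matches_analytic_double_exponential(self, free_dexsy):
        sm = free_dexsy
        pred = np.exp(-(sm.b1[:, None] + sm.b2[None, :]) * D0)
        assert np.all(np.abs(sm.values - pred) < 4 * sm.stderr + 1e-4)

    def test_monotone_nonincreasing_in_each_gradient(self, free_dexsy):
        # monotone up to the Monte Carlo noise of each pair of cells
        v, e = free_dexsy.values, free_dexsy.stderr
        tol0 = 4 * (e[1:, :] + e[:-1, :])
        tol1 = 4 * (e[:, 1:] + e[:, :-1])
        assert np.all(np.diff(v, axis=0) <= tol0)
        assert np.all(np.diff(v, axis=1) <= tol1)

    def test_dosy_matches_analytic(self):
        params = WalkParams(n_walkers=10_000, duration=0.05, n_steps=2000,
                            seed=22)
        S, b, err = synthesize_dosy(None, G_list=np.linspace(0, 0.2, 16),
                                    substrate=None, params=params)
        np.testing.assert_allclose(S, np.exp(-b * D0),
                                   atol=4 * err.max() + 1e-4)


class TestSubstrateSynthesis:
    def test_signal_symmetric_under_gradient_swap(self, exchange_sphere_run):
        v = exchange_sphere_run["signal"].values
        err = exchange_sphere_run["signal"].stderr
        tol = 4 * (err + err.T) + 1e-3
        assert np.all(np.abs(v - v.T) < tol)

    def test_two_seeds_agree_within_sampling_error(self, sphere_substrate):
        seq = DexsySequence(G1=np.linspace(0, 0.9, 4),
                            G2=np.linspace(0, 0.9, 4))
        mats = []
        for seed in (31, 32):
            params = WalkParams(n_walkers=4000, duration=0.17,
                                n_steps=6800, transit_prob=0.0, seed=seed)
            mats.append(synthesize_dexsy(None, seq,
                                         substrate=sphere_substrate,
                                         params=params))
        a, b = mats
        tol = 4 * np.hypot(a.stderr, b.stderr) + 1e-4
        assert np.all(np.abs(a.values - b.values) < tol)

    def test_fexsy_adc_recovers_with_mixing_time_when_permeable(
            self, sphere_sweep):
        # ADC(tm=0) < ADC(tm=300ms) once exchange refills the fast pool
        from dexsy.fexsy import fit_adc
        # re-synthesize from the sweep's phase integrals is implicit in the
        # summary: AXR > 0 for permeable members
        assert (sphere_sweep.summary["axr_per_s"].iloc[1:] > 0).all()

    def test_fexsy_no_filter_no_exchange_keeps_adc_flat(
            self, sphere_substrate):
        from dexsy.fexsy import fit_adc
        params = WalkParams(n_walkers=4000, duration=0.37, n_steps=14800,
                            transit_prob=0.0, seed=33)
        fa = synthesize_fexsy(None, filter_G=0.0, substrate=sphere_substrate,
                              params=params)
        adcs = [fit_adc(fa.signals[:, j], fa.b_encode)
                for j in range(len(fa.tm_list))]
        # no filter and no exchange: ADC independent of tm within MC error
        # (per-ADC sampling noise at 4000 walkers is ~2e-11 m^2/s)
        assert np.ptp(adcs) / np.mean(adcs) < 0.12


def test_signal_matrix_io_roundtrip(tmp_path):
    seq = DexsySequence(G1=np.linspace(0, 0.64, 16),
                        G2=np.linspace(0, 0.64, 16))
    rng = np.random.default_rng(0)
    v = np.exp(-rng.uniform(0, 3, (16, 16)))
    v[0, 0] = 1.0
    from dexsy.acquisition import SignalMatrix
    sm = SignalMatrix(v, seq.G1, seq.G2, 15e-3, 17e-3, 0.2)
    path = tmp_path / "m.txt"
    write_signal_matrix(sm, path)
    back = read_signal_matrix(path)
    np.testing.assert_allclose(back.values, sm.values)
    np.testing.assert_allclose(back.b1, sm.b1)


def test_signal_matrix_parse_errors(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("# delta = 0.015\n# Delta = 0.017\n# tm = 0.2\n"
                    "0 0.1 0.2\n0.1 0.9 0.8\n0.2 0.8 0.7\n")
    with pytest.raises(ValueError, match="S0"):
        read_signal_matrix(path)
    path.write_text("# Delta = 0.017\n# tm = 0.2\n0 0.1\n0 1.0\n")
    with pytest.raises(ValueError, match="delta"):
        read_signal_matrix(path)
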