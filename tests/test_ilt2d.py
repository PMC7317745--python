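"""Inverse Laplace inversion: recovery, regularization policy, degeneracies,
and the FISTA/NNLS cross-check."""

import numpy as np
import pytest

from dexsy.acquisition import SignalMatrix, b_value, forward_signal
from dexsy.ilt2d import (DiffusivityGrid, InversionError, _compress, _fista,
                         invert_1d, invert_2d, read_spectrum, select_alpha,
                         write_spectrum)

G16 = np.linspace(0.0, 0.9, 16)
B16 = b_value(G16, 15e-3, 17e-3)


def _signal_from_cells(grid, cells_weights, noise_sd=0.0, seed=0):
    F = np.zeros((grid.n_points, grid.n_points))
    for (i, j), w in cells_weights.items():
        F[i, j] = w
    S = forward_signal(F, grid.values, grid.values, B16, B16)
    stderr = None
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0, noise_sd, S.shape)
        S[0, 0] = 1.0
        stderr = np.full(S.shape, noise_sd)
    return SignalMatrix(S, G16, G16, 15e-3, 17e-3, 0.1, stderr=stderr)


class TestRecovery:
    def test_one_component_recovered_within_one_cell(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(25, 25): 1.0})
        spec = invert_2d(sm, grid=grid)
        m = spec.amplitudes
        assert m[24:27, 24:27].sum() / m.sum() >= 0.95
        assert spec.residual <= 0.01

    def test_two_components_two_diagonal_peaks(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(20, 20): 0.5, (41, 41): 0.5})
        spec = invert_2d(sm, grid=grid)
        m = spec.amplitudes
        assert m[19:22, 19:22].sum() >= 0.35
        assert m[40:43, 40:43].sum() >= 0.35
        assert spec.residual <= 0.01

    def test_round_trip_residual_below_one_percent(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(18, 18): 0.4, (40, 40): 0.4,
                                       (18, 40): 0.1, (40, 18): 0.1})
        spec = invert_2d(sm, grid=grid)
        recon = forward_signal(spec.amplitudes, grid.values, grid.values,
                               sm.b1, sm.b2)
        rel = np.linalg.norm(recon - sm.values) / np.linalg.norm(sm.values)
        assert rel <= 0.01
        assert rel == pytest.approx(spec.residual, rel=1e-6)

    def test_nonnegative_and_mass_near_unity(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(30, 30): 1.0})
        spec = invert_2d(sm, grid=grid)
        assert np.all(spec.amplitudes >= 0)
        assert 0.9 <= spec.total <= 1.1

    def test_deterministic(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(25, 25): 1.0})
        a = invert_2d(sm, grid=grid).amplitudes
        b = invert_2d(sm, grid=grid).amplitudes
        np.testing.assert_array_equal(a, b)


class TestDegenerate:
    def test_all_ones_signal_warns_of_edge_mass(self):
        sm = SignalMatrix(np.ones((16, 16)), G16, G16, 15e-3, 17e-3, 0.1)
        with pytest.warns(UserWarning, match="boundary"):
            spec = invert_2d(sm)
        # mass at the lowest-attenuation (smallest D) edge
        assert spec.amplitudes[0, 0] > 0.5 * spec.total

    def test_constant_b_rejected(self):
        sm = SignalMatrix(np.ones((3, 3)),
                          np.zeros(3), np.zeros(3), 15e-3, 17e-3, 0.1)
        with pytest.raises(InversionError, match="under-determined"):
            invert_2d(sm)
        with pytest.raises(InversionError, match="under-determined"):
            invert_1d(np.ones(4), np.zeros(4))


class TestAlphaSelection:
    def test_fixed_strategy_returns_configured_alpha(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(25, 25): 1.0})
        assert select_alpha(sm, grid, "fixed", fixed_alpha=0.123) == 0.123

    def test_discrepancy_matches_known_noise_level(self):
        grid = DiffusivityGrid.logspace()
        sigma = 0.005
        sm = _signal_from_cells(grid, {(20, 20): 0.5, (40, 40): 0.5},
                                noise_sd=sigma, seed=1)
        alpha = select_alpha(sm, grid, "discrepancy")
        spec = invert_2d(sm, grid=grid, alpha=alpha)
        misfit = spec.residual * np.linalg.norm(sm.values)
        target = np.sqrt(sm.values.size) * sigma
        assert misfit == pytest.approx(target, rel=0.15)

    def test_large_alpha_spreads_the_spectrum(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(25, 25): 1.0})
        sharp = invert_2d(sm, grid=grid, alpha=1e-8).amplitudes
        smooth = invert_2d(sm, grid=grid, alpha=1e2).amplitudes

        def entropy(F):
            p = F / F.sum()
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        assert entropy(smooth) > entropy(sharp)

    def test_unknown_strategy_rejected(self):
        grid = DiffusivityGrid.logspace()
        sm = _signal_from_cells(grid, {(25, 25): 1.0})
        with pytest.raises(ValueError):
            select_alpha(sm, grid, "nonsense")


class TestOneDimensional:
    def test_single_exponential_single_peak(self):
        grid = DiffusivityGrid.logspace()
        b = b_value(np.linspace(0, 0.9, 256), 15e-3, 17e-3)
        D0 = grid.values[30]
        spec = invert_1d(np.exp(-b * D0), b, grid=grid)
        assert spec.amplitudes[29:32].sum() / spec.amplitudes.sum() >= 0.95
        assert np.all(spec.amplitudes >= 0)

    def test_ten_fold_separation_resolved(self):
        grid = DiffusivityGrid.logspace()
        b = b_value(np.linspace(0, 0.9, 256), 15e-3, 17e-3)
        DA = grid.values[25]
        S = 0.5 * (np.exp(-b * DA) + np.exp(-b * DA * 10))
        spec = invert_1d(S, b, grid=grid)
        amp = spec.amplitudes
        maxima = [i for i in range(1, len(amp) - 1)
                  if amp[i] > amp[i - 1] and amp[i] >= amp[i + 1]
                  and amp[i] > 0.01 * amp.max()]
        assert len(maxima) == 2

    def test_1p5_fold_separation_merges(self):
        grid = DiffusivityGrid.logspace()
        b = b_value(np.linspace(0, 0.9, 256), 15e-3, 17e-3)
        DA = grid.values[30]
        S = 0.5 * (np.exp(-b * DA) + np.exp(-b * DA * 1.5))
        spec = invert_1d(S, b, grid=grid)
        amp = spec.amplitudes
        maxima = [i for i in range(1, len(amp) - 1)
                  if amp[i] > amp[i - 1] and amp[i] >= amp[i + 1]
                  and amp[i] > 0.01 * amp.max()]
        assert len(maxima) == 1


class TestSolverCrossCheck:
    def test_fista_matches_active_set_nnls_on_reduced_problem(self):
        # independent oracle: scipy's Lawson-Hanson on the explicit
        # Kronecker system at a size where it is affordable
        from scipy.optimize import nnls
        grid = DiffusivityGrid.logspace(n=16)
        K = np.exp(-np.outer(B16, grid.values))
        U, Kc, smax = _compress(K)
        F = np.zeros((16, 16))
        F[5, 5], F[11, 11] = 0.6, 0.4
        S = K @ F @ K.T
        Sc = U.T @ S @ U
        alpha = 1e-6 * smax**4
        F_fista = _fista(Kc, Kc, Sc, alpha, max_iter=60000, tol=1e-16)
        A = np.kron(Kc, Kc)
        A_aug = np.vstack([A, np.sqrt(alpha) * np.eye(256)])
        y = np.concatenate([Sc.ravel(), np.zeros(256)])
        x, _ = nnls(A_aug, y)
        np.testing.assert_allclose(F_fista.ravel(), x, atol=5e-4)


def test_grid_validation_and_cell_size():
    with pytest.raises(ValueError):
        DiffusivityGrid(np.array([1e-9, 1e-10]))
    grid = DiffusivityGrid.logspace(1e-12, 1e-8, 64)
    assert grid.cell_log10 == pytest.approx(4 / 63)


def test_spectrum_io_roundtrip(tmp_path):
    grid = DiffusivityGrid.logspace()
    sm = _signal_from_cells(grid, {(25, 25): 1.0})
    spec = invert_2d(sm, grid=grid)
    write_spectrum(spec, tmp_path / "s.txt")
    back = read_spectrum(tmp_path / "s.txt")
    np.testing.assert_allclose(back.amplitudes, spec.amplitudes)
    assert back.alpha == spec.alpha
    assert back.truncation == spec.truncation
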