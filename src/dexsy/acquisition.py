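"""DEXSY / DOSY / FEXSY signal synthesis from random-walk ensembles.

A double diffusion encoding (DEXSY) sequence applies two pulsed-gradient
spin-echo (PGSE) pairs of amplitudes ``G1`` and ``G2`` separated by a mixing
time ``tm``.  The noiseless normalized signal obeys

    S/S0 = sum_{D1, D2} p(D1, D2) exp(-b1 D1) exp(-b2 D2),

with ``b = gamma^2 delta^2 G^2 (Delta - delta/3)`` per PGSE pair.  The
simulated signal is synthesized from walker phase integrals: each pair's
effective gradient waveform (sign-reversed second lobe) is integrated along
the walker's unwrapped trajectory at every simulation time step (finite
pulses — no narrow-pulse shortcut), and the ensemble signal is the cosine
mean over walkers.

Pulse timings are rounded to whole simulation steps; the b-values used
downstream are recomputed from the rounded timings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montecarlo import (PhaseIntegrals, WalkEnsemble, WalkParams,
                         simulate_phase_integrals)

__all__ = [
    "GAMMA_H",
    "PgsePair",
    "DexsySequence",
    "SignalMatrix",
    "FexsyAcquisition",
    "b_value",
    "forward_signal",
    "forward_signal_1d",
    "pair_waveform",
    "dexsy_waveforms",
    "fexsy_waveforms",
    "synthesize_dexsy",
    "synthesize_dosy",
    "synthesize_fexsy",
    "write_signal_matrix",
    "read_signal_matrix",
]

#: Gyromagnetic ratio of 1H, rad s^-1 T^-1.
GAMMA_H = 2.675e8


def b_value(G, delta: float, Delta: float, gamma: float = GAMMA_H):
    """Diffusion weighting ``b = gamma^2 delta^2 G^2 (Delta - delta/3)`` (s/m^2)."""
    if delta > Delta:
        raise ValueError("pulse duration delta cannot exceed separation Delta")
    if delta <= 0:
        raise ValueError("delta must be positive")
    G = np.asarray(G, dtype=float)
    return gamma**2 * delta**2 * G**2 * (Delta - delta / 3.0)


@dataclass(frozen=True)
class PgsePair:
    """One pulsed-gradient pair: amplitude G (T/m), duration delta (s),
    separation Delta (s), gradient direction (unit 3-vector)."""

    G: float
    delta: float
    Delta: float
    direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.delta > self.Delta:
            raise ValueError("delta must not exceed Delta")
        if not np.isclose(np.linalg.norm(self.direction), 1.0):
            raise ValueError("direction must be a unit vector")

    @property
    def b(self) -> float:
        return float(b_value(self.G, self.delta, self.Delta))


@dataclass(frozen=True)
class DexsySequence:
    """Double diffusion encoding: two PGSE pair timings, a mixing time and
    the gradient amplitude grids.

    The mixing time ``tm`` runs from the end of the first pair's second lobe
    to the start of the second pair.  Defaults are the simulated protocol:
    delta = 15 ms, Delta = 17 ms, tm = 100 ms, G1 = G2 = 0-900 mT/m in 16
    linearly spaced steps.
    """

    delta: float = 15e-3
    Delta: float = 17e-3
    tm: float = 100e-3
    G1: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.9, 16))
    G2: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.9, 16))
    direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.tm < 0:
            raise ValueError("tm must be non-negative")
        if self.delta > self.Delta:
            raise ValueError("delta must not exceed Delta")
        for name, g in (("G1", self.G1), ("G2", self.G2)):
            g = np.asarray(g, float)
            if g[0] != 0.0:
                raise ValueError(f"{name} must start at 0 (S0 cell)")
            if np.any(np.diff(g) < 0):
                raise ValueError(f"{name} must be non-decreasing")

    @property
    def total_time(self) -> float:
        return 2.0 * (self.Delta + self.delta) + self.tm


@dataclass
class SignalMatrix:
    """Normalized DEXSY signal ``S/S0`` on the ``(G1, G2)`` amplitude grid.

    ``stderr`` (optional) holds the per-cell Monte Carlo standard error,
    which downstream inversion can use as a noise estimate.  ``delta``,
    ``Delta`` are the step-rounded timings actually integrated.
    """

    values: np.ndarray
    G1: np.ndarray
    G2: np.ndarray
    delta: float
    Delta: float
    tm: float
    gamma: float = GAMMA_H
    direction: tuple | None = None
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.G1 = np.asarray(self.G1, float)
        self.G2 = np.asarray(self.G2, float)
        if self.values.shape != (len(self.G1), len(self.G2)):
            raise ValueError("values shape must be (len(G1), len(G2))")
        if not (self.G1[0] == 0.0 and self.G2[0] == 0.0):
            raise ValueError("gradient grids must include the G=0 (S0) cell")
        if not np.isclose(self.values[0, 0], 1.0, atol=1e-9):
            raise ValueError("values[0, 0] must equal 1 (S/S0 normalization)")

    @property
    def b1(self) -> np.ndarray:
        return b_value(self.G1, self.delta, self.Delta, self.gamma)

    @property
    def b2(self) -> np.ndarray:
        return b_value(self.G2, self.delta, self.Delta, self.gamma)


@dataclass
class FexsyAcquisition:
    """Filtered diffusion signals: a fixed-amplitude first pair (the filter)
    followed, after each mixing time, by a variable encoding pair.

    ``signals[i, j]`` is S/S0 at encode amplitude ``encode_G[i]`` and mixing
    time ``tm_list[j]`` (S0 = no gradients at all).
    """

    filter_G: float
    encode_G: np.ndarray
    tm_list: np.ndarray
    signals: np.ndarray
    delta: float
    Delta: float
    gamma: float = GAMMA_H

    @property
    def b_encode(self) -> np.ndarray:
        return b_value(self.encode_G, self.delta, self.Delta, self.gamma)


# ---------------------------------------------------------------------------
# closed-form forward model
# ---------------------------------------------------------------------------

def forward_signal(weights, D1, D2, b1, b2) -> np.ndarray:
    """Evaluate the double-exponential sum over a (D1, D2) weight grid.

    ``weights[k, l]`` is the probability mass at ``(D1[k], D2[l])``; the
    result has shape ``(len(b1), len(b2))``.
    """
    weights = np.asarray(weights, float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    K1 = np.exp(-np.outer(np.asarray(b1, float), np.asarray(D1, float)))
    K2 = np.exp(-np.outer(np.asarray(b2, float), np.asarray(D2, float)))
    return K1 @ weights @ K2.T


def forward_signal_1d(weights, D, b) -> np.ndarray:
    """Single-encoding analogue: ``S(b) = sum_k w_k exp(-b D_k)``."""
    weights = np.asarray(weights, float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    return np.exp(-np.outer(np.asarray(b, float),
                            np.asarray(D, float))) @ weights


# ---------------------------------------------------------------------------
# waveform construction (unit-amplitude effective gradients)
# ---------------------------------------------------------------------------

def _round_steps(t: float, dt: float) -> int:
    return int(round(t / dt))

def pair_waveform(n_steps: int, dt: float, t_start: float, delta: float,
                  Delta: float) -> tuple[np.ndarray, float, float]:
    """Unit effective waveform of one PGSE pair starting at ``t_start``.

    Lobe one is +1 for ``delta``, lobe two is -1 for ``delta`` starting at
    ``t_start + Delta`` (the spin-echo effective sign).  Returns the
    waveform and the step-rounded ``(delta, Delta)`` actually laid down.
    """
    i0 = _round_steps(t_start, dt)
    i_delta = max(1, _round_steps(delta, dt))
    i_Delta = _round_steps(Delta, dt)
    if i_delta > i_Delta:
        raise ValueError("rounded delta exceeds rounded Delta")
    end = i0 + i_Delta + i_delta
    if end > n_steps:
        raise ValueError(
            f"sequence needs {end} steps but the simulation has {n_steps}"
        )
    w = np.zeros(n_steps)
    w[i0:i0 + i_delta] = 1.0
    w[i0 + i_Delta:end] = -1.0
    return w, i_delta * dt, i_Delta * dt


def dexsy_waveforms(seq: DexsySequence, n_steps: int, dt: float):
    """Both pair waveforms for a DEXSY sequence; returns
    ``(W (2, n_steps), delta_rounded, Delta_rounded)``."""
    w1, d_r, D_r = pair_waveform(n_steps, dt, 0.0, seq.delta, seq.Delta)
    t2 = D_r + d_r + seq.tm
    w2, _, _ = pair_waveform(n_steps, dt, t2, seq.delta, seq.Delta)
    return np.stack([w1, w2]), d_r, D_r


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _integrals_from_ensemble(ens: WalkEnsemble, W: np.ndarray,
                             direction) -> np.ndarray:
    """Phase integrals from a stored trajectory (save_every == 1 path)."""
    if ens.save_every != 1:
        raise ValueError("stored-trajectory synthesis needs save_every == 1")
    e = np.asarray(direction, float)
    proj = ens.positions[:, 1:, :] @ e  # position at the end of each step
    return proj @ W.T * ens.params.dt


def _resolve_integrals(walk, W, direction, n_expected):
    if isinstance(walk, WalkEnsemble):
        return _integrals_from_ensemble(walk, W, direction), walk.params
    if isinstance(walk, PhaseIntegrals):
        if walk.integrals.shape[1] < n_expected:
            raise ValueError("phase-integral walk lacks the needed waveforms")
        return walk.integrals[:, :n_expected], walk.params
    raise TypeError("walk must be a WalkEnsemble or PhaseIntegrals")


def _cos_mean(phase: np.ndarray) -> tuple[float, float]:
    c = np.cos(phase)
    return float(c.mean()), float(c.std(ddof=1) / np.sqrt(len(c)))


def synthesize_dexsy(walk, seq: DexsySequence, substrate=None,
                     params: WalkParams | None = None) -> SignalMatrix:
    """DEXSY signal matrix from a walk.

    ``walk`` may be a :class:`WalkEnsemble` (stored trajectories), a
    :class:`PhaseIntegrals` whose first two waveforms are the DEXSY pairs,
    or ``None`` — in which case ``substrate`` and ``params`` are used to run
    the phase-integral simulation here.
    """
    if walk is None:
        if params is None:
            raise ValueError("params required when walk is None")
        W, _, _ = dexsy_waveforms(seq, params.n_steps, params.dt)
        walk = simulate_phase_integrals(substrate, params, W,
                                        np.asarray(seq.direction, float))
    if isinstance(walk, WalkEnsemble):
        W, d_r, D_r = dexsy_waveforms(seq, walk.params.n_steps,
                                      walk.params.dt)
        integ = _integrals_from_ensemble(walk, W, seq.direction)
    else:
        integ, p = _resolve_integrals(walk, None, None, 2)
        _, d_r, D_r = dexsy_waveforms(seq, p.n_steps, p.dt)

    n1, n2 = len(seq.G1), len(seq.G2)
    S = np.empty((n1, n2))
    err = np.empty((n1, n2))
    gamma = GAMMA_H
    for i, g1 in enumerate(seq.G1):
        for j, g2 in enumerate(seq.G2):
            S[i, j], err[i, j] = _cos_mean(
                gamma * (g1 * integ[:, 0] + g2 * integ[:, 1]))
    return SignalMatrix(values=S, G1=np.asarray(seq.G1, float),
                        G2=np.asarray(seq.G2, float), delta=d_r, Delta=D_r,
                        tm=seq.tm, gamma=gamma, direction=seq.direction,
                        stderr=err)


def synthesize_dosy(walk, delta: float = 15e-3, Delta: float = 17e-3,
                    G_list=None, direction=(1.0, 0.0, 0.0),
                    substrate=None, params: WalkParams | None = None):
    """Single-PGSE (DOSY) attenuation curve.

    Returns ``(signals, b, stderr)`` over ``G_list`` (default 0-900 mT/m in
    256 steps).  ``walk`` follows the same convention as
    :func:`synthesize_dexsy` (for :class:`PhaseIntegrals`, waveform 0 must
    be the PGSE pair at t = 0).
    """
    if G_list is None:
        G_list = np.linspace(0.0, 0.9, 256)
    G_list = np.asarray(G_list, float)
    if walk is None:
        if params is None:
            raise ValueError("params required when walk is None")
        w, d_r, D_r = pair_waveform(params.n_steps, params.dt, 0.0, delta,
                                    Delta)
        walk = simulate_phase_integrals(substrate, params, w[None, :],
                                        np.asarray(direction, float))
        integ = walk.integrals[:, 0]
    elif isinstance(walk, WalkEnsemble):
        w, d_r, D_r = pair_waveform(walk.params.n_steps, walk.params.dt,
                                    0.0, delta, Delta)
        integ = _integrals_from_ensemble(walk, w[None, :], direction)[:, 0]
    else:
        integ = walk.integrals[:, 0]
        d_r = round(delta / walk.params.dt) * walk.params.dt
        D_r = round(Delta / walk.params.dt) * walk.params.dt
    S = np.empty(len(G_list))
    err = np.empty(len(G_list))
    for i, g in enumerate(G_list):
        S[i], err[i] = _cos_mean(GAMMA_H * g * integ)
    return S, b_value(G_list, d_r, D_r), err


def fexsy_waveforms(delta: float, Delta: float, tm_list, n_steps: int,
                    dt: float):
    """Waveform stack for a FEXSY acquisition: filter pair at t = 0, then
    one encode-pair waveform per mixing time."""
    tm_list = np.asarray(tm_list, float)
    wf, d_r, D_r = pair_waveform(n_steps, dt, 0.0, delta, Delta)
    rows = [wf]
    for tm in tm_list:
        we, _, _ = pair_waveform(n_steps, dt, D_r + d_r + tm, delta, Delta)
        rows.append(we)
    return np.stack(rows), d_r, D_r


def synthesize_fexsy(walk, filter_G: float = 68e-3, encode_list=None,
                     delta: float = 15e-3, Delta: float = 17e-3,
                     tm_list=(0.0, 10e-3, 100e-3, 200e-3, 300e-3),
                     direction=(1.0, 0.0, 0.0), substrate=None,
                     params: WalkParams | None = None) -> FexsyAcquisition:
    """FEXSY signals: fixed filter pair, variable encode pair per mixing time.

    Defaults are the simulated protocol: filter 68 mT/m, encoding 0-68 mT/m
    in 9 steps, tm = 0, 10, 100, 200, 300 ms.  For :class:`PhaseIntegrals`
    input, waveforms must be ``[filter, encode@tm_0, encode@tm_1, ...]`` as
    produced by :func:`fexsy_waveforms`.
    """
    if encode_list is None:
        encode_list = np.linspace(0.0, 68e-3, 9)
    encode_list = np.asarray(encode_list, float)
    tm_list = np.asarray(tm_list, float)
    if walk is None:
        if params is None:
            raise ValueError("params required when walk is None")
        W, d_r, D_r = fexsy_waveforms(delta, Delta, tm_list, params.n_steps,
                                      params.dt)
        walk = simulate_phase_integrals(substrate, params, W,
                                        np.asarray(direction, float))
        integ = walk.integrals
    elif isinstance(walk, WalkEnsemble):
        W, d_r, D_r = fexsy_waveforms(delta, Delta, tm_list,
                                      walk.params.n_steps, walk.params.dt)
        integ = _integrals_from_ensemble(walk, W, direction)
    else:
        integ = walk.integrals
        if integ.shape[1] != 1 + len(tm_list):
            raise ValueError("phase integrals do not match the tm schedule")
        d_r = round(delta / walk.params.dt) * walk.params.dt
        D_r = round(Delta / walk.params.dt) * walk.params.dt

    S = np.empty((len(encode_list), len(tm_list)))
    for j in range(len(tm_list)):
        for i, ge in enumerate(encode_list):
            phase = GAMMA_H * (filter_G * integ[:, 0] + ge * integ[:, 1 + j])
            S[i, j] = np.cos(phase).mean()
    return FexsyAcquisition(filter_G=filter_G, encode_G=encode_list,
                            tm_list=tm_list, signals=S, delta=d_r, Delta=D_r)


# ---------------------------------------------------------------------------
# delimited-text signal matrix format (also the ingestion format for
# acquired DEXSY data)
# ---------------------------------------------------------------------------

def write_signal_matrix(sm: SignalMatrix, path) -> None:
    """First row/column hold the G2/G1 amplitudes (T/m), body holds S/S0."""
    with open(path, "w") as fh:
        fh.write("# dexsy signal matrix\n")
        fh.write(f"# delta = {sm.delta!r}\n")
        fh.write(f"# Delta = {sm.Delta!r}\n")
        fh.write(f"# tm = {sm.tm!r}\n")
        fh.write(f"# gamma = {sm.gamma!r}\n")
        if sm.direction is not None:
            fh.write("# direction = %s\n"
                     % " ".join(repr(float(x)) for x in sm.direction))
        body = np.zeros((len(sm.G1) + 1, len(sm.G2) + 1))
        body[0, 1:] = sm.G2
        body[1:, 0] = sm.G1
        body[1:, 1:] = sm.values
        np.savetxt(fh, body, fmt="%.17g")


def read_signal_matrix(path) -> SignalMatrix:
    """Parse a signal-matrix file, validating grid monotonicity and the S0
    cell; b-values are recomputed from the header timings."""
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    header[key.strip()] = val.strip()
                continue
            rows.append([float(x) for x in line.split()])
    for key in ("delta", "Delta", "tm"):
        if key not in header:
            raise ValueError(f"signal matrix header missing {key!r}")
    body = np.asarray(rows)
    if body.ndim != 2 or body.shape[0] < 2 or body.shape[1] < 2:
        raise ValueError("signal matrix body must be at least 2x2")
    G1, G2 = body[1:, 0], body[0, 1:]
    if G1[0] != 0.0 or G2[0] != 0.0:
        raise ValueError("signal matrix is missing the G=0 (S0) row/column")
    if np.any(np.diff(G1) < 0) or np.any(np.diff(G2) < 0):
        raise ValueError("gradient amplitude lists must be non-decreasing")
    direction = None
    if "direction" in header:
        direction = tuple(float(x) for x in header["direction"].split())
    return SignalMatrix(
        values=body[1:, 1:], G1=G1, G2=G2,
        delta=float(header["delta"]), Delta=float(header["Delta"]),
        tm=float(header["tm"]),
        gamma=float(header.get("gamma", GAMMA_H)),
        direction=direction,
    )
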