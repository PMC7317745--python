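"""Monte Carlo diffusion with finitely permeable membranes.

The walker model: fixed step length ``sqrt(6 D dt)``, direction uniform on
the sphere, specular reflection at membranes, and transmission with a
per-encounter probability ``p`` related to the membrane permeability ``k``
(m/s) by

    p = k * sqrt(6 * dt / D)

so that the macroscopic exchange rate is independent of the time step.  Two
simulation surfaces are provided:

* :func:`simulate` stores unwrapped trajectories (and per-step compartment
  labels) — the inspectable path, for small ensembles.
* :func:`simulate_phase_integrals` accumulates gradient phase integrals on
  the fly for a set of effective gradient waveforms — the production path,
  with O(n_walkers) memory.  The two paths agree exactly for matching seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _walk
from .substrates import EXTRACELLULAR, CylinderSubstrate, SphereSubstrate

__all__ = [
    "WalkParams",
    "WalkEnsemble",
    "PhaseIntegrals",
    "transit_probability",
    "permeability_from_probability",
    "simulate",
    "simulate_phase_integrals",
    "locate_many",
]


def transit_probability(k: float, dt: float, D: float) -> float:
    """Membrane transit probability per encounter for permeability ``k``.

    ``p = k * sqrt(6 dt / D)``, clipped to [0, 1].
    """
    if dt <= 0 or D <= 0:
        raise ValueError("dt and D must be positive")
    if k < 0:
        raise ValueError("permeability must be non-negative")
    return float(min(1.0, k * np.sqrt(6.0 * dt / D)))


def permeability_from_probability(p: float, dt: float, D: float) -> float:
    """Exact inverse of :func:`transit_probability`: ``k = p sqrt(D/(6 dt))``."""
    if dt <= 0 or D <= 0:
        raise ValueError("dt and D must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(p * np.sqrt(D / (6.0 * dt)))


@dataclass(frozen=True)
class WalkParams:
    """Random-walk configuration.

    Defaults are the full-scale study conditions: 100 000 walkers for
    400 ms in 16 000 steps (dt = 25 us) at an intrinsic diffusivity of
    2.0e-9 m^2/s.  ``transit_prob`` is the per-encounter membrane crossing
    probability ``p``.
    """

    n_walkers: int = 100_000
    duration: float = 0.4
    n_steps: int = 16_000
    diffusivity: float = 2.0e-9
    transit_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_walkers < 1 or self.n_steps < 1:
            raise ValueError("n_walkers and n_steps must be >= 1")
        if self.duration <= 0 or self.diffusivity <= 0:
            raise ValueError("duration and diffusivity must be positive")
        if not 0.0 <= self.transit_prob <= 1.0:
            raise ValueError("transit_prob must lie in [0, 1]")

    @property
    def dt(self) -> float:
        return self.duration / self.n_steps

    @property
    def step_length(self) -> float:
        return float(np.sqrt(6.0 * self.diffusivity * self.dt))

    @property
    def permeability(self) -> float:
        """Membrane permeability (m/s) implied by ``transit_prob``."""
        return permeability_from_probability(self.transit_prob, self.dt,
                                             self.diffusivity)


@dataclass(frozen=True)
class WalkEnsemble:
    """Stored trajectories: unwrapped positions and compartment labels.

    ``positions`` has shape ``(n_walkers, n_saved, 3)`` with slot 0 the
    initial position; ``labels`` holds the compartment of the matching
    periodic image (object index or ``EXTRACELLULAR``).
    """

    positions: np.ndarray
    labels: np.ndarray
    save_every: int
    params: WalkParams

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        dt = self.params.dt
        return np.arange(self.positions.shape[1]) * self.save_every * dt

    def displacements(self) -> np.ndarray:
        """Unwrapped displacement from the initial position."""
        return self.positions - self.positions[:, :1, :]


@dataclass(frozen=True)
class PhaseIntegrals:
    """On-the-fly phase path integrals for a set of unit waveforms.

    ``integrals[w, s] = sum_t W[s, t] * x_w(t).e * dt`` (units m.s); the
    spin phase for gradient amplitude G is ``gamma * G * integrals``.
    ``labels_start``/``labels_end`` are compartment labels at t=0 and t=end.
    """

    integrals: np.ndarray
    labels_start: np.ndarray
    labels_end: np.ndarray
    direction: np.ndarray
    params: WalkParams


# ---------------------------------------------------------------------------
# candidate grids for the kernels
# ---------------------------------------------------------------------------

def _aabb_dist2_periodic(points, lo, hi, box, ndim):
    """Min-image squared distance from each point to each axis-aligned cell."""
    # points: (n, ndim); lo/hi: (m, ndim) -> (m, n)
    d2 = np.zeros((lo.shape[0], points.shape[0]))
    for ax in range(ndim):
        p = points[None, :, ax]
        l = lo[:, None, ax]
        h = hi[:, None, ax]
        d = np.maximum(np.maximum(l - p, p - h), 0.0)
        # try shifted images of the point
        for shift in (-box, box):
            ps = p + shift
            d = np.minimum(d, np.maximum(np.maximum(l - ps, ps - h), 0.0))
        d2 += d * d
    return d2


def _build_grid(centers, radii, box, ndim, reach):
    """CSR candidate lists: objects whose surface is within ``reach`` of a cell."""
    rmax = float(np.max(radii))
    ncell = max(1, int(box / (rmax + reach)))
    ncell = min(ncell, 24)
    edges = np.linspace(0.0, box, ncell + 1)
    grids = np.meshgrid(*[np.arange(ncell)] * ndim, indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    lo = edges[idx]
    hi = edges[idx + 1]
    d2 = _aabb_dist2_periodic(centers[:, :ndim], lo, hi, box, ndim)
    mask = d2 <= (np.asarray(radii)[None, :] + reach) ** 2
    counts = mask.sum(axis=1)
    cell_start = np.zeros(len(lo) + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    cell_items = np.nonzero(mask)[1].astype(np.int64)
    return ncell, cell_start, cell_items


#: Periodic box side used when simulating free diffusion (substrate=None).
FREE_BOX = 2e-5


def _kernel_inputs(substrate, params: WalkParams):
    reach = params.step_length * 1.05 + 10 * _walk.NUDGE
    if substrate is None:  # free diffusion: no membranes at all
        ncell = 1
        cs = np.zeros(2, dtype=np.int64)
        ci = np.zeros(0, dtype=np.int64)
        return (_walk.walk_spheres,
                (np.zeros((0, 3)), 0.0, FREE_BOX, cs, ci, ncell))
    box = (substrate.box_side if isinstance(substrate, SphereSubstrate)
           else substrate.lattice_size)
    if params.step_length >= box / 4:
        raise ValueError(
            "step length is too large relative to the periodic cell for "
            "minimum-image membrane detection"
        )
    if isinstance(substrate, SphereSubstrate):
        ncell, cs, ci = _build_grid(substrate.centers,
                                    np.full(substrate.n_spheres,
                                            substrate.radius),
                                    substrate.box_side, 3, reach)
        return (_walk.walk_spheres,
                (substrate.centers, substrate.radius, substrate.box_side,
                 cs, ci, ncell))
    if isinstance(substrate, CylinderSubstrate):
        ncell, cs, ci = _build_grid(substrate.centers, substrate.radii,
                                    substrate.lattice_size, 2, reach)
        return (_walk.walk_cylinders,
                (substrate.centers, substrate.radii, substrate.lattice_size,
                 cs, ci, ncell))
    raise TypeError(f"unsupported substrate type {type(substrate).__name__}")


def _run_kernel(substrate, params: WalkParams, waveforms, direction,
                save_every):
    kernel, geo = _kernel_inputs(substrate, params)
    n = params.n_walkers
    if waveforms is None:
        waveforms = np.zeros((0, params.n_steps))
    waveforms = np.ascontiguousarray(waveforms, dtype=np.float64)
    if waveforms.shape[1] != params.n_steps:
        raise ValueError("waveforms must have n_steps columns")
    e = np.zeros(3) if direction is None else np.asarray(direction, float)
    if direction is not None and not np.isclose(np.linalg.norm(e), 1.0):
        raise ValueError("gradient direction must be a unit vector")
    n_saved = params.n_steps // save_every + 1 if save_every > 0 else 1
    traj = np.zeros((n if save_every > 0 else 1, n_saved, 3))
    integ = np.zeros((n, waveforms.shape[0]))
    pos0 = np.zeros((n, 3))
    posT = np.zeros((n, 3))
    errors = np.zeros(n, dtype=np.int64)
    kernel(*geo, n, params.n_steps, params.dt, params.step_length,
           params.transit_prob, params.seed, waveforms,
           e[0], e[1], e[2], save_every, traj, integ, pos0, posT, errors)
    n_bad = int(np.count_nonzero(errors))
    if n_bad:
        if n_bad > 1e-3 * n:
            raise RuntimeError(
                f"{n_bad}/{n} walkers exceeded {_walk.MAX_INTERACTIONS} "
                "membrane interactions in a single step: geometry is "
                "pathologically tight"
            )
        import warnings
        warnings.warn(
            f"{n_bad}/{n} walkers had a step truncated after "
            f"{_walk.MAX_INTERACTIONS} membrane interactions "
            f"({int(errors.sum())} events total)", stacklevel=3)
    return traj, integ, pos0, posT


def simulate(substrate, params: WalkParams, save_every: int = 1,
             memory_limit_bytes: float = 2e9) -> WalkEnsemble:
    """Run the walk storing unwrapped trajectories every ``save_every`` steps.

    Intended for modest ensembles; raises if the trajectory array would
    exceed ``memory_limit_bytes`` (use :func:`simulate_phase_integrals` for
    production signal synthesis instead).
    """
    if save_every < 1:
        raise ValueError("save_every must be >= 1")
    n_saved = params.n_steps // save_every + 1
    need = params.n_walkers * n_saved * 3 * 8
    if need > memory_limit_bytes:
        raise MemoryError(
            f"trajectory storage would need {need:.2e} bytes; increase "
            "save_every or use simulate_phase_integrals"
        )
    traj, _, _, _ = _run_kernel(substrate, params, None, None, save_every)
    flat = traj.reshape(-1, 3)
    labels = locate_many(substrate, flat).reshape(traj.shape[:2])
    return WalkEnsemble(positions=traj, labels=labels,
                        save_every=save_every, params=params)


def simulate_phase_integrals(substrate, params: WalkParams,
                             waveforms: np.ndarray,
                             direction) -> PhaseIntegrals:
    """Run the walk accumulating phase integrals for each unit waveform.

    ``waveforms`` is ``(n_seq, n_steps)``: the effective (sign-reversed
    second lobe) gradient shape at unit amplitude.  ``direction`` is the
    gradient unit vector shared by all waveforms.
    """
    _, integ, pos0, posT = _run_kernel(substrate, params, waveforms,
                                       direction, 0)
    return PhaseIntegrals(
        integrals=integ,
        labels_start=locate_many(substrate, pos0),
        labels_end=locate_many(substrate, posT),
        direction=np.asarray(direction, float),
        params=params,
    )


def save_phase_integrals(ph: PhaseIntegrals, path) -> None:
    """Binary checkpoint (.npz) with a YAML text sidecar recording the
    walk parameters and seed."""
    import yaml

    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             integrals=ph.integrals, labels_start=ph.labels_start,
             labels_end=ph.labels_end, direction=ph.direction)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".yaml", "w") as fh:
        yaml.safe_dump({"walk_params": {
            "n_walkers": ph.params.n_walkers,
            "duration": ph.params.duration,
            "n_steps": ph.params.n_steps,
            "diffusivity": ph.params.diffusivity,
            "transit_prob": ph.params.transit_prob,
            "seed": ph.params.seed,
        }}, fh)


def load_phase_integrals(path) -> PhaseIntegrals:
    import yaml

    path = str(path)
    npz = path if path.endswith(".npz") else path + ".npz"
    base = path[:-4] if path.endswith(".npz") else path
    data = np.load(npz)
    with open(base + ".yaml") as fh:
        meta = yaml.safe_load(fh)["walk_params"]
    return PhaseIntegrals(
        integrals=data["integrals"], labels_start=data["labels_start"],
        labels_end=data["labels_end"], direction=data["direction"],
        params=WalkParams(**meta),
    )


def locate_many(substrate, points) -> np.ndarray:
    """Vectorized compartment labels for an ``(n, 3)`` array of points."""
    pts = np.asarray(points, dtype=float)
    if substrate is None:
        return np.full(len(pts), EXTRACELLULAR, dtype=np.int64)
    if isinstance(substrate, SphereSubstrate):
        box = substrate.box_side
        tree = cKDTree(substrate.centers % box, boxsize=box)
        dist, idx = tree.query(pts[:, :3] % box)
        return np.where(dist < substrate.radius, idx, EXTRACELLULAR)
    L = substrate.lattice_size
    labels = np.full(len(pts), EXTRACELLULAR, dtype=np.int64)
    # 100 cylinders: direct min-image test in manageable chunks
    for start in range(0, len(pts), 65536):
        chunk = pts[start:start + 65536, :2]
        d = chunk[:, None, :] - substrate.centers[None, :, :]
        d -= L * np.round(d / L)
        inside = np.einsum("ijk,ijk->ij", d, d) < substrate.radii[None, :] ** 2
        any_in = inside.any(axis=1)
        labels[start:start + 65536][any_in] = np.argmax(
            inside[any_in], axis=1)
    return labels
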