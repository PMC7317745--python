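"""Shared fixtures: substrates and the reduced-scale simulation runs that
several analysis-level tests interrogate.

The expensive Monte Carlo sweeps are session-scoped and shared; their sizes
(walker counts, durations) are the package's reduced study scale, chosen so
the whole suite runs on one CPU in well under half an hour.
"""

import numpy as np
import pytest

from dexsy.acquisition import DexsySequence, dexsy_waveforms, \
    synthesize_dexsy, synthesize_dosy
from dexsy.ilt2d import invert_1d, invert_2d
from dexsy.montecarlo import WalkParams, simulate_phase_integrals
from dexsy.pipeline import RunConfig, run_pipeline
from dexsy.spectra import find_peaks
from dexsy.substrates import build_cylinder_substrate, build_sphere_substrate

SEED = 7
#: Transit probabilities spanning the four-peak regime (0.37-2.0 um/s).
PROBS = np.linspace(1e-4, 5.5e-4, 6)


@pytest.fixture(scope="session")
def sphere_substrate():
    return build_sphere_substrate(seed=SEED)


@pytest.fixture(scope="session")
def cylinder_substrate():
    return build_cylinder_substrate(seed=SEED)


@pytest.fixture(scope="session")
def sphere_sweep():
    """DEXSY + FEXSY permeability sweep in the yeast-like sphere packing."""
    cfg = RunConfig(substrate={"kind": "spheres"},
                    probabilities=list(PROBS),
                    n_walkers=20000, duration=0.37, n_steps=14800,
                    seed=SEED)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def cylinder_sweep():
    """DEXSY-only permeability sweep in the nerve-bundle cylinder lattice."""
    cfg = RunConfig(substrate={"kind": "cylinders"},
                    probabilities=list(PROBS),
                    n_walkers=20000, duration=0.17, n_steps=6800,
                    seed=SEED, run_fexsy=False)
    return run_pipeline(cfg)


def _dexsy_run(substrate, p, n_walkers=10000):
    seq = DexsySequence()
    params = WalkParams(n_walkers=n_walkers, duration=0.17, n_steps=6800,
                        transit_prob=p, seed=SEED)
    W, _, _ = dexsy_waveforms(seq, params.n_steps, params.dt)
    ph = simulate_phase_integrals(substrate, params, W,
                                  np.asarray(seq.direction))
    sm = synthesize_dexsy(ph, seq)
    spec = invert_2d(sm)
    return dict(ph=ph, signal=sm, spectrum=spec, peaks=find_peaks(spec),
                params=params, seq=seq)


@pytest.fixture(scope="session")
def impermeable_sphere_run(sphere_substrate):
    """p = 0 in the sphere packing, with the DOSY projection alongside."""
    out = _dexsy_run(sphere_substrate, 0.0)
    S, b, err = synthesize_dosy(out["ph"])
    out["dosy"] = invert_1d(S, b, stderr=err)
    return out


@pytest.fixture(scope="session")
def collapse_sphere_run(sphere_substrate):
    """p = 0.1: fast exchange collapses the spectrum to a single peak."""
    return _dexsy_run(sphere_substrate, 0.1)


@pytest.fixture(scope="session")
def exchange_sphere_run(sphere_substrate):
    """p = 0.0003: the four-peak regime with visible cross peaks."""
    return _dexsy_run(sphere_substrate, 0.0003)
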