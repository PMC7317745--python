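"""End-to-end pipeline: substrate -> walks -> signals -> spectra -> DEI/AXR.

One :func:`run_pipeline` call sweeps a list of membrane transit
probabilities, running for each a single phase-accumulating walk whose
waveform stack covers the DEXSY pairs and (optionally) the DOSY pair and the
FEXSY filter/encode pairs, then inverts, segments peaks, and computes the
DEI and AXR.  The summary table (probability, permeability, DEI, AXR) and
the Spearman rank correlations against permeability are the pipeline's
headline outputs.

Every stochastic stage derives its seed from the configured base seed (walk
seed for probability index ``i`` is ``seed + i``); the effective
configuration and its hash are written next to the outputs, so a re-run of
the same config reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acquisition as acq
from . import fexsy as fx
from . import ilt2d, spectra, substrates
from .montecarlo import WalkParams, permeability_from_probability, \
    simulate_phase_integrals

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ingest_acquired"]

log = logging.getLogger("dexsy")


@dataclass
class RunConfig:
    """Configuration for a permeability sweep.

    ``substrate``: {"kind": "spheres"|"cylinders"|"free", ...builder args}.
    ``probabilities``: membrane transit probabilities to sweep.
    Sub-dicts override the protocol defaults of each stage.
    """

    substrate: dict = field(default_factory=lambda: {"kind": "spheres"})
    probabilities: list = field(default_factory=lambda: list(
        np.linspace(1e-4, 5.5e-4, 10)))
    n_walkers: int = 100_000
    duration: float = 0.4
    n_steps: int = 16_000
    diffusivity: float = 2.0e-9
    seed: int = 0
    sequence: dict = field(default_factory=dict)     # DexsySequence kwargs
    run_dosy: bool = False
    run_fexsy: bool = True
    fexsy_params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)         # DiffusivityGrid kwargs
    alpha_strategy: str = "auto"
    peak_threshold: float = spectra.DEFAULT_THRESHOLD
    diagonal_tolerance: float = spectra.DEFAULT_DIAGONAL_TOL
    outdir: str | None = None

    def config_hash(self) -> str:
        """Hash of the science-relevant configuration (outdir excluded, so
        the same sweep written to two places hashes identically)."""
        payload = _jsonable(asdict(self))
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    dei_rho: float | None
    axr_rho: float | None
    spectra: list
    peak_lists: list
    config: RunConfig
    config_hash: str


def build_substrate(spec: dict, default_seed: int = 0):
    """Construct a substrate from its config dict."""
    spec = dict(spec)
    kind = spec.pop("kind", "spheres")
    spec.setdefault("seed", default_seed)
    if kind == "free":
        return None
    if kind == "spheres":
        return substrates.build_sphere_substrate(**spec)
    if kind == "cylinders":
        return substrates.build_cylinder_substrate(**spec)
    raise ValueError(f"unknown substrate kind {kind!r}")


def _default_direction(substrate):
    """Perpendicular to the cylinder axes (restriction-sensitive); x for
    isotropic substrates."""
    return (1.0, 0.0, 0.0)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full permeability sweep described by ``config``."""
    t_start = time.time()
    chash = config.config_hash()
    outdir = None
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump({"config_hash": chash,
                            **_jsonable(asdict(config))}, fh)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    log.info("pipeline start: config %s", chash)

    substrate = build_substrate(config.substrate, config.seed)
    direction = np.asarray(
        config.sequence.get("direction", _default_direction(substrate)),
        float)
    seq = acq.DexsySequence(**{**config.sequence,
                               "direction": tuple(direction)})
    grid = ilt2d.DiffusivityGrid.logspace(**config.grid)

    fex_kwargs = dict(filter_G=68e-3,
                      encode_list=np.linspace(0.0, 68e-3, 9),
                      tm_list=np.array([0.0, 10e-3, 100e-3, 200e-3, 300e-3]))
    fex_kwargs.update(config.fexsy_params)

    rows = []
    all_spectra, all_peaks = [], []
    for i, p in enumerate(config.probabilities):
        t0 = time.time()
        # Common random numbers across the sweep: walker paths share one
        # seed so cross-p differences are driven by the transit probability,
        # not resampling noise.
        params = WalkParams(n_walkers=config.n_walkers,
                            duration=config.duration,
                            n_steps=config.n_steps,
                            diffusivity=config.diffusivity,
                            transit_prob=float(p), seed=config.seed)
        W_dex, _, _ = acq.dexsy_waveforms(seq, params.n_steps, params.dt)
        stack = [W_dex]
        if config.run_fexsy:
            W_fex, _, _ = acq.fexsy_waveforms(seq.delta, seq.Delta,
                                              fex_kwargs["tm_list"],
                                              params.n_steps, params.dt)
            stack.append(W_fex)
        W = np.vstack(stack)
        ph = simulate_phase_integrals(substrate, params, W, direction)
        t_walk = time.time() - t0

        sm = acq.synthesize_dexsy(ph, seq)
        spec = ilt2d.invert_2d(sm, grid=grid,
                               alpha_strategy=config.alpha_strategy)
        peaks = spectra.find_peaks(
            spec, amplitude_threshold_fraction=config.peak_threshold,
            diagonal_tolerance=config.diagonal_tolerance)
        try:
            dei = spectra.compute_dei(peaks).dei
        except ValueError:
            dei = np.nan

        axr = np.nan
        if config.run_fexsy:
            from .montecarlo import PhaseIntegrals
            ph_fex = PhaseIntegrals(
                integrals=ph.integrals[:, 2:],
                labels_start=ph.labels_start, labels_end=ph.labels_end,
                direction=ph.direction, params=ph.params)
            fa = acq.synthesize_fexsy(ph_fex, delta=seq.delta,
                                      Delta=seq.Delta, direction=direction,
                                      **fex_kwargs)
            try:
                axr = fx.axr_from_fexsy(fa).axr
            except (ValueError, RuntimeError) as exc:
                log.warning("AXR fit failed at p=%g: %s", p, exc)

        k = permeability_from_probability(float(p), params.dt,
                                          params.diffusivity)
        rows.append({"probability": float(p), "permeability_m_per_s": k,
                     "dei": dei, "axr_per_s": axr, "seed": params.seed})
        all_spectra.append(spec)
        all_peaks.append(peaks)
        log.info("p=%-9g k=%.3g um/s walk %.1fs total %.1fs dei=%.4g "
                 "axr=%.4g", p, k * 1e6, t_walk, time.time() - t0, dei, axr)
        if outdir is not None:
            tag = f"p{i:02d}"
            acq.write_signal_matrix(sm, outdir / f"signal_{tag}.txt")
            ilt2d.write_spectrum(spec, outdir / f"spectrum_{tag}.txt")
            spectra.write_peak_table(peaks, outdir / f"peaks_{tag}.tsv")

    summary = pd.DataFrame(rows)
    dei_rho = axr_rho = None
    valid = summary.dropna(subset=["dei"])
    if len(valid) >= 3 and valid["dei"].nunique() > 1:
        dei_rho = spectra.dei_permeability_curve(
            valid["dei"], valid["permeability_m_per_s"])
    valid = summary.dropna(subset=["axr_per_s"])
    if len(valid) >= 3 and valid["axr_per_s"].nunique() > 1:
        axr_rho = fx.axr_permeability_curve(
            valid["axr_per_s"], valid["permeability_m_per_s"])
    log.info("pipeline done in %.1fs: dei_rho=%s axr_rho=%s",
             time.time() - t_start, dei_rho, axr_rho)
    if outdir is not None:
        with open(outdir / "summary.tsv", "w") as fh:
            fh.write(f"# config_hash = {chash}\n")
            if dei_rho is not None:
                fh.write(f"# dei_spearman_rho = {dei_rho!r}\n")
            if axr_rho is not None:
                fh.write(f"# axr_spearman_rho = {axr_rho!r}\n")
            summary.to_csv(fh, sep="\t", index=False)
    return PipelineResult(summary=summary, dei_rho=dei_rho, axr_rho=axr_rho,
                          spectra=all_spectra, peak_lists=all_peaks,
                          config=config, config_hash=chash)


def ingest_acquired(path, **metadata) -> acq.SignalMatrix:
    """Read an acquired DEXSY signal matrix from the delimited-text format,
    overriding header fields with any keyword metadata."""
    sm = acq.read_signal_matrix(path)
    for key, val in metadata.items():
        if not hasattr(sm, key):
            raise AttributeError(f"SignalMatrix has no field {key!r}")
        setattr(sm, key, val)
    return sm


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (keys as in the dataclass)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.pop("config_hash", None)
    return RunConfig(**data)
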