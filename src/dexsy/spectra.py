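"""Peak analysis of diffusion-diffusion spectra and the DEI statistic.

Peaks on the identity line of a DEXSY spectrum are spins with the same
diffusivity in both encoding periods (non-exchanging pools); off-diagonal
peaks are spins that moved between environments during the mixing time.
Following the usual two-compartment reading, the diagonal peaks are labeled
``A`` (higher diffusivity, extracellular) and ``B`` (lower diffusivity,
intracellular), the off-diagonal peaks ``C`` (above the diagonal) and ``D``
(below).  The Diffusion Exchange Index is the volume ratio

    DEI = (V_C + V_D) / (V_A + V_B),

a normalized, model-free measure of exchange.  Peaks far above the
diffusivity range of A (more than a decade) are left unassigned
(perfusion-like) and excluded from the DEI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .ilt2d import Spectrum2D

__all__ = [
    "Peak",
    "DeiResult",
    "find_peaks",
    "compute_dei",
    "dei_permeability_curve",
    "write_peak_table",
]

#: Default amplitude threshold, as a fraction of the spectral maximum, below
#: which cells are ignored (suppresses low-level inversion artifacts).
DEFAULT_THRESHOLD = 0.01
#: Default half-width (log10 units) of the band around the identity line
#: within which a peak counts as diagonal.
DEFAULT_DIAGONAL_TOL = 0.15
#: Peaks whose centroids are within this many grid cells are merged (the
#: split-diagonal-peak artifact of the inversion).
MERGE_CELLS = 2.0
#: Diffusivity (m^2/s) above which a diagonal peak cannot be tissue water;
#: used to anchor the A label below perfusion-like components.
FREE_WATER_CEILING = 5e-9


@dataclass(frozen=True)
class Peak:
    """One segmented spectral peak."""

    centroid: tuple          # (D1, D2) in m^2/s
    volume: float            # summed amplitude
    label: str               # 'A', 'B', 'C', 'D' or 'unassigned'
    n_cells: int = 0
    max_amplitude: float = 0.0

    @property
    def log_centroid(self) -> tuple:
        return (float(np.log10(self.centroid[0])),
                float(np.log10(self.centroid[1])))


@dataclass(frozen=True)
class DeiResult:
    dei: float
    exchange_volume: float
    nonexchange_volume: float
    peaks: tuple
    excluded: tuple = ()


def _segment(A: np.ndarray, threshold_fraction: float):
    """Label map of above-threshold regions, split at internal maxima."""
    mask = A >= threshold_fraction * A.max()
    regions = cc_label(mask, connectivity=2)
    out = np.zeros_like(regions)
    next_id = 1
    for rid in range(1, regions.max() + 1):
        rmask = regions == rid
        local = peak_local_max(np.where(rmask, A, 0.0), min_distance=2,
                               exclude_border=False,
                               threshold_rel=0.0, labels=rmask.astype(int))
        if len(local) <= 1:
            out[rmask] = next_id
            next_id += 1
            continue
        markers = np.zeros_like(regions)
        for k, (i, j) in enumerate(local, start=1):
            markers[i, j] = k
        ws = watershed(-A, markers=markers, mask=rmask)
        for k in range(1, len(local) + 1):
            out[ws == k] = next_id
            next_id += 1
    return out, next_id - 1


def _raw_peaks(spec: Spectrum2D, threshold_fraction: float):
    A = spec.amplitudes
    if A.max() <= 0:
        return []
    seg, n = _segment(A, threshold_fraction)
    logD = spec.grid.log10
    peaks = []
    for rid in range(1, n + 1):
        ii, jj = np.nonzero(seg == rid)
        w = A[ii, jj]
        tot = w.sum()
        if tot <= 0:
            continue
        l1 = float(np.sum(w * logD[ii]) / tot)
        l2 = float(np.sum(w * logD[jj]) / tot)
        peaks.append(dict(l1=l1, l2=l2, volume=float(tot),
                          n_cells=len(ii), max_amp=float(w.max())))
    return peaks


def _merge_close(peaks, cell: float):
    """Merge peaks whose centroids are within MERGE_CELLS grid cells."""
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                d = np.hypot(peaks[i]["l1"] - peaks[j]["l1"],
                             peaks[i]["l2"] - peaks[j]["l2"]) / cell
                if d <= MERGE_CELLS:
                    a, b = peaks[i], peaks[j]
                    tot = a["volume"] + b["volume"]
                    peaks[i] = dict(
                        l1=(a["l1"] * a["volume"] + b["l1"] * b["volume"]) / tot,
                        l2=(a["l2"] * a["volume"] + b["l2"] * b["volume"]) / tot,
                        volume=tot, n_cells=a["n_cells"] + b["n_cells"],
                        max_amp=max(a["max_amp"], b["max_amp"]))
                    del peaks[j]
                    merged = True
                    break
            if merged:
                break
    return peaks


def find_peaks(spec: Spectrum2D,
               amplitude_threshold_fraction: float = DEFAULT_THRESHOLD,
               diagonal_tolerance: float = DEFAULT_DIAGONAL_TOL) -> list:
    """Segment and label the peaks of a diffusion-diffusion spectrum.

    Connected regions of amplitude >= ``amplitude_threshold_fraction`` of
    the maximum are split at distinct internal maxima (watershed), close
    fragments are re-merged, and each resulting peak is classified:
    diagonal (|log10 D1 - log10 D2| <= ``diagonal_tolerance`` at the
    centroid, boundary inclusive) versus off-diagonal, with diagonal peaks
    labeled A (higher D) / B (lower D), off-diagonal C (above) / D (below),
    and peaks more than a decade above A unassigned.
    """
    if not 0.0 < amplitude_threshold_fraction < 1.0:
        raise ValueError("threshold fraction must lie in (0, 1)")
    raw = _raw_peaks(spec, amplitude_threshold_fraction)
    if not raw:
        return []
    raw = _merge_close(raw, spec.grid.cell_log10)

    diag = [p for p in raw
            if abs(p["l1"] - p["l2"]) <= diagonal_tolerance]
    diag_ids = {id(p) for p in diag}
    off = [p for p in raw if id(p) not in diag_ids]

    # Identify the extracellular anchor A first: the highest-D diagonal
    # peak at or below the free-water ceiling (perfusion pseudo-diffusion
    # lives far above it).  Anything more than a decade above A is
    # perfusion-like and left unassigned before labelling.
    labels = {}
    outlier_ids = set()
    if diag:
        ceiling = np.log10(FREE_WATER_CEILING)
        below = [p for p in diag
                 if 0.5 * (p["l1"] + p["l2"]) <= ceiling] or diag
        anchor = max(below, key=lambda p: p["l1"] + p["l2"])
        anchor_level = 0.5 * (anchor["l1"] + anchor["l2"])
        for p in raw:
            if min(p["l1"], p["l2"]) > anchor_level + 1.0:
                outlier_ids.add(id(p))
                labels[id(p)] = "unassigned"
    core = [p for p in diag if id(p) not in outlier_ids]
    if core:
        order = sorted(range(len(core)), key=lambda k: core[k]["l1"]
                       + core[k]["l2"])
        lo, hi = order[0], order[-1]
        if len(core) == 1:
            labels[id(core[lo])] = "A"
        else:
            for p in core:
                # co-label intermediate fragments with the nearer extreme
                d_lo = abs(p["l1"] + p["l2"] - core[lo]["l1"] - core[lo]["l2"])
                d_hi = abs(p["l1"] + p["l2"] - core[hi]["l1"] - core[hi]["l2"])
                labels[id(p)] = "A" if d_hi <= d_lo else "B"
    for p in off:
        if id(p) not in outlier_ids:
            labels[id(p)] = "C" if p["l2"] > p["l1"] else "D"

    out = []
    for p in raw:
        out.append(Peak(centroid=(10.0 ** p["l1"], 10.0 ** p["l2"]),
                        volume=p["volume"], label=labels[id(p)],
                        n_cells=p["n_cells"], max_amplitude=p["max_amp"]))
    out.sort(key=lambda pk: pk.label)
    return out


def compute_dei(peaks) -> DeiResult:
    """Diffusion Exchange Index from a labeled peak list.

    ``DEI = (sum C + sum D volumes) / (sum A + sum B volumes)``; unassigned
    peaks are excluded and reported separately.
    """
    peaks = list(peaks)
    diag = [p for p in peaks if p.label in ("A", "B")]
    if not diag:
        raise ValueError("DEI needs at least one diagonal (A/B) peak")
    non_exchange = sum(p.volume for p in diag)
    if non_exchange <= 0:
        raise ValueError("non-exchange volume is zero: DEI undefined")
    exchange = sum(p.volume for p in peaks if p.label in ("C", "D"))
    excluded = tuple(p for p in peaks if p.label == "unassigned")
    return DeiResult(dei=float(exchange / non_exchange),
                     exchange_volume=float(exchange),
                     nonexchange_volume=float(non_exchange),
                     peaks=tuple(peaks), excluded=excluded)


def dei_permeability_curve(dei_values, permeabilities) -> float:
    """Spearman rank correlation of DEI against membrane permeability
    (average-rank tie handling)."""
    dei_values = np.asarray(dei_values, float)
    permeabilities = np.asarray(permeabilities, float)
    if len(dei_values) != len(permeabilities):
        raise ValueError("lists must have equal length")
    if len(dei_values) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(dei_values) == 0 or np.ptp(permeabilities) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho = spearmanr(dei_values, permeabilities).statistic
    return float(rho)


def write_peak_table(peaks, path, dei: DeiResult | None = None) -> None:
    """Delimited peak table (label, centroid D1, centroid D2, volume),
    optionally with the DEI record appended as comments."""
    with open(path, "w") as fh:
        fh.write("label\tD1_m2_per_s\tD2_m2_per_s\tvolume\n")
        for p in peaks:
            fh.write(f"{p.label}\t{p.centroid[0]:.6e}\t{p.centroid[1]:.6e}"
                     f"\t{p.volume:.6e}\n")
        if dei is not None:
            fh.write(f"# dei = {dei.dei!r}\n")
            fh.write(f"# exchange_volume = {dei.exchange_volume!r}\n")
            fh.write(f"# nonexchange_volume = {dei.nonexchange_volume!r}\n")
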