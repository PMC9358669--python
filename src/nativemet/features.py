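"""Chromatographic feature detection.

Two trace types feed the matching stage: deconvoluted neutral-mass traces
from the native (protein-infusion) run, and m/z traces built from MS1
centroids of the metabolomics run.  Both are reduced to features --
resolved peaks with an apex, boundaries and a trapezoidal area -- by the
same detector.  The protein side additionally keeps "persistent" features
for species present across most of the gradient (the constantly infused
apo protein never elutes as a peak).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from nativemet.deconvolution import MassTrace
from nativemet.io import Run, Spectrum

__all__ = [
    "Feature",
    "detect_peaks",
    "build_protein_features",
    "build_metabolite_features",
    "coelution_correlation",
    "features_to_table",
]

_feature_counter = itertools.count(1)


@dataclass
class Feature:
    """A resolved chromatographic peak in (mass or m/z) x RT space."""

    id: str
    kind: str  # "protein" | "metabolite"
    mass_value: float  # neutral Da (protein) or precursor m/z (metabolite)
    rt_apex: float
    rt_start: float
    rt_end: float
    apex_intensity: float
    area: float
    trace_rt: np.ndarray = field(default_factory=lambda: np.array([]))
    trace_intensity: np.ndarray = field(default_factory=lambda: np.array([]))
    msms_scan_ids: list[str] = field(default_factory=list)
    persistent: bool = False  # species present across most of the run (apo)


def _next_id(kind: str) -> str:
    return f"{kind[0].upper()}{next(_feature_counter):05d}"


def detect_peaks(
    rt: np.ndarray,
    intensity: np.ndarray,
    min_height: float = 0.0,
    min_width: float = 0.05,
    smoothing: int = 5,
    kind: str = "metabolite",
    mass_value: float = 0.0,
) -> list[Feature]:
    """Detect peaks on an rt-sorted trace.

    The trace is smoothed with a ``smoothing``-point moving average, local
    maxima above ``min_height`` become apex candidates, and boundaries are
    walked outward to the surrounding minima or first baseline (zero)
    crossing.  Peaks narrower than ``min_width`` minutes are dropped; the
    area is the trapezoidal integral of the raw trace over the boundaries.
    """
    rt = np.asarray(rt, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    n = rt.size
    if n < 3:
        return []
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        smooth = np.convolve(intensity, kernel, mode="same")
    else:
        smooth = intensity
    apexes, _ = _signal.find_peaks(smooth, height=max(min_height, 0.0) or None)
    out = []
    for apex in apexes:
        # Walk left/right on the smoothed trace to the bracketing minimum
        # or baseline crossing.
        lo = apex
        while lo > 0 and smooth[lo - 1] < smooth[lo] and smooth[lo - 1] > 0:
            lo -= 1
        hi = apex
        while hi < n - 1 and smooth[hi + 1] < smooth[hi] and smooth[hi + 1] > 0:
            hi += 1
        if hi - lo < 2 or rt[hi] - rt[lo] < min_width:
            continue
        seg_rt = rt[lo: hi + 1]
        seg_int = intensity[lo: hi + 1]
        apex_raw = lo + int(np.argmax(seg_int))
        if intensity[apex_raw] < min_height:
            continue
        area = float(np.trapezoid(seg_int, seg_rt))
        if area <= 0:
            continue
        out.append(
            Feature(
                id=_next_id(kind),
                kind=kind,
                mass_value=mass_value,
                rt_apex=float(rt[apex_raw]),
                rt_start=float(rt[lo]),
                rt_end=float(rt[hi]),
                apex_intensity=float(intensity[apex_raw]),
                area=area,
                trace_rt=seg_rt.copy(),
                trace_intensity=seg_int.copy(),
            )
        )
    out.sort(key=lambda f: f.rt_apex)
    return out


def build_protein_features(
    traces: list[MassTrace],
    min_height: float = 0.0,
    min_width: float = 0.05,
    smoothing: int = 5,
    persistent_span_frac: float = 0.8,
) -> list[Feature]:
    """Features from deconvoluted mass traces.

    A trace covering at least ``persistent_span_frac`` of the run's rt span
    is reported as one persistent whole-trace feature (the infused apo
    protein); other traces go through peak detection.
    """
    features: list[Feature] = []
    for tr in traces:
        nz = np.nonzero(tr.intensity)[0]
        if nz.size == 0:
            continue
        run_span = tr.rt[-1] - tr.rt[0]
        cover = tr.rt[nz[-1]] - tr.rt[nz[0]]
        if run_span > 0 and cover / run_span >= persistent_span_frac:
            apex = int(np.argmax(tr.intensity))
            features.append(
                Feature(
                    id=_next_id("protein"),
                    kind="protein",
                    mass_value=tr.center_mass,
                    rt_apex=float(tr.rt[apex]),
                    rt_start=float(tr.rt[nz[0]]),
                    rt_end=float(tr.rt[nz[-1]]),
                    apex_intensity=float(tr.intensity[apex]),
                    area=tr.area,
                    trace_rt=tr.rt.copy(),
                    trace_intensity=tr.intensity.copy(),
                    persistent=True,
                )
            )
        else:
            features.extend(
                detect_peaks(
                    tr.rt,
                    tr.intensity,
                    min_height=min_height,
                    min_width=min_width,
                    smoothing=smoothing,
                    kind="protein",
                    mass_value=tr.center_mass,
                )
            )
    features.sort(key=lambda f: (f.rt_apex, f.mass_value))
    _renumber(features, "P")
    return features


def _renumber(features: list[Feature], prefix: str) -> None:
    # ids are assigned after the final sort so tables are reproducible
    # run-to-run (the detection-time counter is process-global).
    for i, f in enumerate(features, start=1):
        f.id = f"{prefix}{i:05d}"


def _bin_mz(all_peaks: np.ndarray, mz_tol_ppm: float) -> list[slice]:
    """Slices over m/z-sorted peaks separating bins by > tol gaps."""
    bins = []
    start = 0
    for i in range(1, all_peaks.shape[0]):
        gap_tol = mz_tol_ppm * 1e-6 * all_peaks[i, 0]
        if all_peaks[i, 0] - all_peaks[i - 1, 0] > gap_tol:
            bins.append(slice(start, i))
            start = i
    bins.append(slice(start, all_peaks.shape[0]))
    return bins


def build_metabolite_features(
    run: Run,
    mz_tol: float = 10.0,
    min_height: float = 0.0,
    min_width: float = 0.05,
    smoothing: int = 5,
) -> tuple[list[Feature], dict[str, Spectrum]]:
    """Metabolite feature table from an MS1+MS2 metabolomics run.

    MS1 centroids are tolerance-linked across scans into m/z traces
    (``mz_tol`` ppm), peak detection produces features, and each feature is
    linked to the MS2 scans whose precursor m/z lies within tolerance of
    the feature m/z and whose rt falls inside the peak boundaries.

    Returns the features plus a scan_id -> Spectrum map of the run's MS2
    scans (for downstream networking).
    """
    ms1 = run.ms1()
    ms2 = run.ms2()
    rts = np.array([s.rt for s in ms1])
    rows = []
    for i, s in enumerate(ms1):
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((mz, i, inten))
    features: list[Feature] = []
    if rows:
        arr = np.array(sorted(rows), dtype=float)
        for sl in _bin_mz(arr, mz_tol):
            seg = arr[sl]
            w = seg[:, 2].sum()
            mz_center = float((seg[:, 0] * seg[:, 2]).sum() / w) if w > 0 else float(seg[0, 0])
            trace = np.zeros(len(ms1))
            for mz, i_scan, inten in seg:
                trace[int(i_scan)] += inten
            features.extend(
                detect_peaks(
                    rts,
                    trace,
                    min_height=min_height,
                    min_width=min_width,
                    smoothing=smoothing,
                    kind="metabolite",
                    mass_value=mz_center,
                )
            )
    features.sort(key=lambda f: (f.rt_apex, f.mass_value))
    _renumber(features, "M")
    spectra = {s.scan_id: s for s in ms2}
    for f in features:
        tol = mz_tol * 1e-6 * f.mass_value
        for s in ms2:
            if s.precursor is None:
                continue
            if (
                abs(s.precursor[0] - f.mass_value) <= tol
                and f.rt_start <= s.rt <= f.rt_end
            ):
                f.msms_scan_ids.append(s.scan_id)
    features.sort(key=lambda f: (f.rt_apex, f.mass_value))
    return features, spectra


def coelution_correlation(f1: Feature, f2: Feature) -> float:
    """Pearson correlation of two features' traces over their rt overlap.

    Both traces are linearly interpolated onto the union rt grid restricted
    to the overlapping range.  Returns NaN when the overlap has fewer than
    three points or either trace is constant there; callers treat NaN as 0.
    """
    lo = max(f1.rt_start, f2.rt_start)
    hi = min(f1.rt_end, f2.rt_end)
    if hi <= lo or f1.trace_rt.size < 2 or f2.trace_rt.size < 2:
        return float("nan")
    grid = np.union1d(f1.trace_rt, f2.trace_rt)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 3:
        return float("nan")
    a = np.interp(grid, f1.trace_rt, f1.trace_intensity)
    b = np.interp(grid, f2.trace_rt, f2.trace_intensity)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(_stats.pearsonr(a, b).statistic)


def features_to_table(features: list[Feature]) -> pd.DataFrame:
    """Native-dialect feature table (one row per feature)."""
    return pd.DataFrame(
        {
            "feature_id": [f.id for f in features],
            "kind": [f.kind for f in features],
            "mass_value": [f.mass_value for f in features],
            "rt_apex": [f.rt_apex for f in features],
            "rt_start": [f.rt_start for f in features],
            "rt_end": [f.rt_end for f in features],
            "apex_intensity": [f.apex_intensity for f in features],
            "area": [f.area for f in features],
            "n_msms": [len(f.msms_scan_ids) for f in features],
            "persistent": [f.persistent for f in features],
        }
    )
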