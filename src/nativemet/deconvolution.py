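"""Charge-state deconvolution of native-MS scans into neutral-mass species.

A protein electrosprayed under native conditions appears as an envelope of
multiply protonated ions; the species' neutral mass M produces one peak per
charge z at (M + z*proton)/z.  Deconvolution inverts this: every (peak,
charge) combination within the allowed charge range is a mass hypothesis,
hypotheses that agree on a neutral mass form a candidate charge series, and
a candidate is accepted only when supported by enough distinct, mutually
consistent charge states.  This charge-series-consistency approach works on
centroided envelopes without isotope structure; the downstream workflow
only consumes neutral masses and summed intensities.

Candidates are ranked by summed intensity and peaks are greedily assigned
to the best candidate first, so each centroid supports at most one species.
Harmonic artifacts (mass hypotheses at k* or 1/k* the true mass that share
the same peaks) are suppressed against already-accepted species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from nativemet.chem import mass_from_mz
from nativemet.io import Run, Spectrum

__all__ = [
    "DeconvolutedSpecies",
    "MassTrace",
    "deconvolve_scan",
    "deconvolve_run",
    "build_mass_traces",
    "extract_xic",
    "detect_apo_depletion",
]

#: Default charge range for ~25 kDa proteins in a 2500-4000 m/z window.
DEFAULT_CHARGE_RANGE: tuple[int, int] = (5, 25)
DEFAULT_PEAK_TOL_PPM: float = 10.0
DEFAULT_MIN_CHARGE_SUPPORT: int = 3
#: Largest gap between successive supporting charges still counted as a
#: near-consecutive series.
MAX_CHARGE_GAP: int = 2


@dataclass
class DeconvolutedSpecies:
    """One neutral-mass hypothesis in one scan."""

    neutral_mass: float
    supporting_charges: tuple[int, ...]
    charge_mz: dict[int, float]
    charge_intensity: dict[int, float]
    total_intensity: float
    scan_id: str = ""
    rt: float = 0.0


@dataclass
class MassTrace:
    """A neutral-mass chromatographic trace across scans."""

    center_mass: float
    rt: np.ndarray
    intensity: np.ndarray
    window: float

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.rt)) if self.rt.size > 1 else 0.0

    @property
    def n_points(self) -> int:
        return int(np.count_nonzero(self.intensity))


def _intra_series_tolerance(mass: float, peak_tol_ppm: float) -> float:
    # Absolute floor keeps low masses from an unrealistically tight window.
    return max(0.05, peak_tol_ppm * 1e-6 * mass)


def _charge_series_ok(charges: Sequence[int], min_support: int) -> bool:
    zs = sorted(set(charges))
    if len(zs) < min_support:
        return False
    gaps = np.diff(zs)
    return bool(np.all(gaps <= MAX_CHARGE_GAP))


@dataclass
class _Candidate:
    mass: float
    members: list  # (peak_index, z, mass, intensity, mz)
    score: float = field(init=False)

    def __post_init__(self) -> None:
        self.score = sum(m[3] for m in self.members)

    def restrict(self, available: np.ndarray) -> "_Candidate":
        return _Candidate(self.mass, [m for m in self.members if available[m[0]]])

    def distinct_charges(self) -> list[int]:
        return sorted({m[1] for m in self.members})

    def peak_indices(self) -> set[int]:
        return {m[0] for m in self.members}


def _cluster_hypotheses(hyps: list, peak_tol_ppm: float) -> list[_Candidate]:
    """Group (peak, z, mass, intensity, mz) hypotheses by neutral mass.

    Hypotheses are swept in mass order; a new cluster starts when the next
    mass falls outside the running intensity-weighted cluster mean by more
    than the intra-series tolerance at that mass.
    """
    if not hyps:
        return []
    hyps = sorted(hyps, key=lambda h: h[2])
    clusters: list[list] = []
    current = [hyps[0]]
    mean = hyps[0][2]
    wsum = hyps[0][3]
    for h in hyps[1:]:
        tol = _intra_series_tolerance(h[2], peak_tol_ppm)
        if abs(h[2] - mean) <= tol:
            current.append(h)
            wsum += h[3]
            mean += (h[2] - mean) * h[3] / wsum if wsum > 0 else 0.0
        else:
            clusters.append(current)
            current = [h]
            mean = h[2]
            wsum = h[3]
    clusters.append(current)
    out = []
    for members in clusters:
        # One hypothesis per (peak, charge): duplicates cannot arise, but a
        # cluster may hold two peaks claiming the same charge; keep the more
        # intense one so the charge series stays one-peak-per-charge.
        best_per_z: dict[int, tuple] = {}
        for m in members:
            if m[1] not in best_per_z or m[3] > best_per_z[m[1]][3]:
                best_per_z[m[1]] = m
        kept = list(best_per_z.values())
        w = sum(m[3] for m in kept)
        mass = sum(m[2] * m[3] for m in kept) / w if w > 0 else kept[0][2]
        out.append(_Candidate(mass, kept))
    return out


def _weighted_mass(members: list) -> float:
    w = sum(m[3] for m in members)
    if w <= 0:
        return float(np.mean([m[2] for m in members]))
    return sum(m[2] * m[3] for m in members) / w


def deconvolve_scan(
    s: Spectrum,
    charge_range: tuple[int, int] = DEFAULT_CHARGE_RANGE,
    peak_tol: float = DEFAULT_PEAK_TOL_PPM,
    min_charge_support: int = DEFAULT_MIN_CHARGE_SUPPORT,
    noise_floor: float | None = None,
) -> list[DeconvolutedSpecies]:
    """Deconvolve one MS1 scan into neutral-mass species.

    Parameters
    ----------
    charge_range : (z_min, z_max) inclusive charge states to consider.
    peak_tol : ppm tolerance between per-charge mass hypotheses of one series.
    min_charge_support : minimum number of distinct near-consecutive charges.
    noise_floor : absolute intensity cutoff; default 3x the scan's median
        peak intensity.
    """
    z_min, z_max = charge_range
    if z_min > z_max:
        raise ValueError(f"invalid charge range {charge_range}")
    if z_min < 1:
        raise ValueError("charges must be >= 1")
    if s.n_peaks == 0:
        return []
    if noise_floor is None:
        # 3x the median intensity of the scan's noise population, taken as
        # the centroids below 10% of the base peak.  Estimating the median
        # over the full peak list would misfire on scans consisting almost
        # entirely of signal envelopes (few noise centroids), where the
        # median is itself a signal peak.
        top = float(np.max(s.intensity))
        low = s.intensity[s.intensity < 0.01 * top]
        noise_floor = 3.0 * float(np.median(low)) if low.size >= 4 else 0.0
        noise_floor = min(noise_floor, 0.05 * top)
    keep = s.intensity > noise_floor
    mzs = s.mz[keep]
    intens = s.intensity[keep]
    n = mzs.size
    if n == 0:
        return []

    hyps = []
    for i in range(n):
        for z in range(z_min, z_max + 1):
            hyps.append((i, z, mass_from_mz(mzs[i], z), float(intens[i]), float(mzs[i])))

    candidates = [
        c
        for c in _cluster_hypotheses(hyps, peak_tol)
        if _charge_series_ok(c.distinct_charges(), min_charge_support)
    ]
    # Greedy assignment: strongest series claims its peaks first.
    candidates.sort(key=lambda c: (-c.score, c.mass))
    available = np.ones(n, dtype=bool)
    accepted: list[_Candidate] = []
    queue = candidates
    while queue:
        cand = queue.pop(0)
        cand = cand.restrict(available)
        if not cand.members or not _charge_series_ok(
            cand.distinct_charges(), min_charge_support
        ):
            continue
        # Re-rank if peak removal changed the ordering.
        if queue and cand.score < queue[0].score:
            queue.append(cand)
            queue.sort(key=lambda c: (-c.score, c.mass))
            continue
        if _is_harmonic(cand, accepted, peak_tol):
            continue
        accepted.append(cand)
        for m in cand.members:
            available[m[0]] = False

    out = []
    for cand in accepted:
        members = sorted(cand.members, key=lambda m: m[1])
        out.append(
            DeconvolutedSpecies(
                neutral_mass=_weighted_mass(members),
                supporting_charges=tuple(m[1] for m in members),
                charge_mz={m[1]: m[4] for m in members},
                charge_intensity={m[1]: m[3] for m in members},
                total_intensity=float(sum(m[3] for m in members)),
                scan_id=s.scan_id,
                rt=s.rt,
            )
        )
    out.sort(key=lambda sp: sp.neutral_mass)
    return out


def _is_harmonic(cand: _Candidate, accepted: list[_Candidate], peak_tol: float) -> bool:
    """True if cand looks like a k* or 1/k* harmonic of an accepted species
    sharing at least half of its peaks (k = 2, 3)."""
    peaks = cand.peak_indices()
    if not peaks:
        return False
    for acc in accepted:
        shared = len(peaks & acc.peak_indices())
        if shared < 0.5 * len(peaks):
            continue
        for k in (2, 3):
            for ratio_mass in (acc.mass * k, acc.mass / k):
                if abs(cand.mass - ratio_mass) <= _intra_series_tolerance(
                    ratio_mass, peak_tol
                ):
                    return True
    return False


def deconvolve_run(run: Run, **params) -> list[list[DeconvolutedSpecies]]:
    """Deconvolve every MS1 scan of a run; one species list per scan."""
    return [deconvolve_scan(s, **params) for s in run.ms1()]


def build_mass_traces(
    run: Run,
    window: float = 5.0,
    min_scans: int = 3,
    max_gap: int = 2,
    species_per_scan: list[list[DeconvolutedSpecies]] | None = None,
    **deconv_params,
) -> list[MassTrace]:
    """Group per-scan deconvoluted species into neutral-mass traces.

    Species across scans are merged while their neutral masses stay within
    ``window`` Da of the trace's running intensity-weighted center; traces
    interrupted for more than ``max_gap`` consecutive scans are split, and
    traces observed in fewer than ``min_scans`` scans are discarded.  The
    returned traces cover the full MS1 rt grid with zeros where the species
    is absent.
    """
    ms1 = run.ms1()
    rts = np.array([s.rt for s in ms1])
    if species_per_scan is None:
        species_per_scan = deconvolve_run(run, **deconv_params)

    open_traces: list[dict] = []
    done: list[dict] = []
    for i_scan, species in enumerate(species_per_scan):
        used = set()
        for tr in list(open_traces):
            if i_scan - tr["last_scan"] > max_gap + 1:
                open_traces.remove(tr)
                done.append(tr)
                continue
            # Best unused species within the window.
            best, best_d = None, window
            for j, sp in enumerate(species):
                if j in used:
                    continue
                d = abs(sp.neutral_mass - tr["center"])
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                sp = species[best]
                used.add(best)
                tr["points"][i_scan] = sp.total_intensity
                tr["wsum"] += sp.total_intensity
                if tr["wsum"] > 0:
                    tr["center"] += (
                        (sp.neutral_mass - tr["center"]) * sp.total_intensity / tr["wsum"]
                    )
                tr["last_scan"] = i_scan
        for j, sp in enumerate(species):
            if j in used:
                continue
            open_traces.append(
                {
                    "center": sp.neutral_mass,
                    "wsum": sp.total_intensity,
                    "points": {i_scan: sp.total_intensity},
                    "last_scan": i_scan,
                }
            )
    done.extend(open_traces)

    traces = []
    for tr in done:
        if len(tr["points"]) < min_scans:
            continue
        intensity = np.zeros(len(ms1))
        for i_scan, v in tr["points"].items():
            intensity[i_scan] = v
        traces.append(
            MassTrace(center_mass=tr["center"], rt=rts.copy(), intensity=intensity, window=window)
        )
    traces.sort(key=lambda t: t.center_mass)
    return traces


def extract_xic(
    run: Run,
    center_mass: float,
    window: float = 5.0,
    species_per_scan: list[list[DeconvolutedSpecies]] | None = None,
    **deconv_params,
) -> tuple[np.ndarray, np.ndarray]:
    """Deconvoluted-mass extracted ion chromatogram (center +- window Da).

    Returns per-MS1-scan summed intensity of deconvoluted species whose
    neutral mass falls within the window; zero where none is present.
    """
    ms1 = run.ms1()
    rts = np.array([s.rt for s in ms1])
    if species_per_scan is None:
        species_per_scan = deconvolve_run(run, **deconv_params)
    intensity = np.zeros(len(ms1))
    for i, species in enumerate(species_per_scan):
        intensity[i] = sum(
            sp.total_intensity
            for sp in species
            if abs(sp.neutral_mass - center_mass) <= window
        )
    return rts, intensity


def detect_apo_depletion(
    rt: np.ndarray,
    intensity: np.ndarray,
    baseline_window: int = 21,
    min_depth_frac: float = 0.3,
) -> list[tuple[float, float]]:
    """Find negative peaks (apo-signal depletion) in an apo-protein XIC.

    The baseline is a rolling median over ``baseline_window`` points; a
    depletion event is a contiguous region where the signal drops below
    (1 - min_depth_frac) * baseline.  Returns (rt at deepest point,
    fractional depth) per event, in rt order.
    """
    rt = np.asarray(rt, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    n = rt.size
    if n == 0:
        return []
    half = max(1, baseline_window // 2)
    baseline = np.array(
        [np.median(intensity[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(baseline > 0, (baseline - intensity) / baseline, 0.0)
    below = depth > min_depth_frac
    events = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            seg = slice(i, j)
            k = i + int(np.argmax(depth[seg]))
            events.append((float(rt[k]), float(depth[k])))
            i = j
        else:
            i += 1
    return events
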