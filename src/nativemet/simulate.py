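"""Synthetic paired native-run / metabolomics-run generator with planted
ground truth.

The generator emulates the acquisition design of a post-column
protein-infusion screen on a 10-min gradient:

* **Native run** -- one MS1 scan stream over m/z 2500-4000.  The apo
  protein (default 25232.6 Da, the deconvoluted mass of bovine
  alpha-chymotrypsin under native conditions) appears in every scan as a
  centroided charge envelope with Gaussian charge abundance (mean 8.5,
  sigma 1.2 over z = 6-11; charge states falling outside the m/z window
  are not recorded, as on the instrument).  Each planted binder adds a
  complex envelope at apo + n x ligand mass whose elution is Gaussian
  (default sigma 0.03 min) and whose ion current is drawn away from the
  apo envelope, so the apo XIC shows the characteristic negative peaks.

* **Metabolomics run** -- MS1 features at [M+H]+ of every planted ligand
  and decoy with matched elution profiles, plus data-dependent MS2 scans
  (up to two per duty cycle, triggered near the apex).  Analog families
  share a fragment ladder whose high-mass rungs are shifted by the
  precursor mass difference, so modified-cosine networking recovers the
  family as one component; decoys carry unrelated ladders.

Envelopes are single centroids per charge state (no isotope structure):
at the resolution and m/z range emulated here the downstream analysis
consumes only neutral masses and intensities.  Noise is multiplicative
log-normal on peak intensities plus a sparse additive floor of random
peaks; every draw is controlled by the scenario seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nativemet.chem import PROTON_MASS, mz_from_mass
from nativemet.io import Run, Spectrum
from nativemet.quant import DoseResponse, TitrationSeries

__all__ = [
    "PlantedBinder",
    "PlantedDecoy",
    "ScreenScenario",
    "GroundTruth",
    "simulate_native_run",
    "simulate_metabolomics_run",
    "simulate_titration",
    "simulate_dose_response",
    "make_family_ladders",
    "default_screen_scenario",
    "proof_of_concept_scan",
]

#: Apo alpha-chymotrypsin deconvoluted mass under native conditions (Da).
DEFAULT_APO_MASS = 25232.6
#: Neutral monoisotopic mass of molassamide, the positive-control binder.
MOLASSAMIDE_MASS = 962.4749


@dataclass(frozen=True)
class PlantedBinder:
    """One ground-truth protein binder."""

    ligand_mass: float  # neutral Da
    rt_apex: float  # minutes
    ratio: float  # complex/apo ion-current ratio at the apex
    width: float = 0.03  # Gaussian sigma, minutes
    stoichiometry: int = 1
    fragments: tuple[tuple[float, float], ...] = ()  # (m/z, rel intensity)
    complex_mass: float | None = None  # override apo + n x ligand
    family: str = ""


@dataclass(frozen=True)
class PlantedDecoy:
    """A metabolite feature that does not bind the protein."""

    mass: float  # neutral Da
    rt_apex: float
    width: float = 0.03
    abundance: float = 1.0
    fragments: tuple[tuple[float, float], ...] = ()
    family: str = ""


@dataclass(frozen=True)
class ScreenScenario:
    """Full specification of a synthetic screen."""

    apo_mass: float = DEFAULT_APO_MASS
    charge_mean: float = 8.5
    charge_sigma: float = 1.2
    z_range: tuple[int, int] = (6, 11)
    mz_window: tuple[float, float] = (2500.0, 4000.0)
    gradient_min: float = 10.0
    native_scan_interval: float = 0.02  # minutes
    metabolomics_scan_interval: float = 0.02
    apo_base_intensity: float = 1.0e6
    metabolite_base_intensity: float = 1.0e6
    binders: tuple[PlantedBinder, ...] = ()
    decoys: tuple[PlantedDecoy, ...] = ()
    noise_sigma: float = 0.05  # log-normal multiplicative sigma
    noise_floor: float = 50.0  # additive noise-peak intensity scale
    noise_peaks_per_scan: int = 5
    mz_jitter_ppm: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted-feature and expected-result tables for a scenario."""

    protein_features: pd.DataFrame
    metabolite_features: pd.DataFrame
    expected_matches: pd.DataFrame
    expected_components: dict[str, set[str]]


def _sub_rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def _envelope(
    mass: float,
    total: float,
    scenario: ScreenScenario,
    strict: bool = True,
) -> list[tuple[int, float, float]]:
    """(z, m/z, intensity) centroids of one species' charge envelope.

    Charge states whose m/z falls outside the acquisition window are
    dropped; if fewer than three remain the species is undetectable by a
    charge-series method and the scenario is rejected.
    """
    z_lo, z_hi = scenario.z_range
    zs = np.arange(z_lo, z_hi + 1)
    weights = np.exp(-0.5 * ((zs - scenario.charge_mean) / scenario.charge_sigma) ** 2)
    weights /= weights.sum()
    peaks = []
    outside = []
    for z, w in zip(zs, weights):
        mz = mz_from_mass(mass, int(z))
        if scenario.mz_window[0] <= mz <= scenario.mz_window[1]:
            peaks.append((int(z), mz, total * float(w)))
        else:
            outside.append(int(z))
    if strict and len(peaks) < 3:
        raise ValueError(
            f"charge envelope of species at {mass:.1f} Da falls outside the "
            f"m/z window {scenario.mz_window}: offending charge states {outside}"
        )
    return peaks


def _gauss(t: np.ndarray | float, apex: float, width: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((t - apex) / width) ** 2)


def _complex_mass(scenario: ScreenScenario, b: PlantedBinder) -> float:
    if b.complex_mass is not None:
        return b.complex_mass
    return scenario.apo_mass + b.stoichiometry * b.ligand_mass


def simulate_native_run(scenario: ScreenScenario) -> tuple[Run, GroundTruth]:
    """Generate the protein-infusion native-MS run for a scenario."""
    for b in scenario.binders:
        if not 0 <= b.rt_apex <= scenario.gradient_min:
            raise ValueError(f"binder rt {b.rt_apex} outside the gradient")
        _envelope(_complex_mass(scenario, b), 1.0, scenario)  # validates window
    _envelope(scenario.apo_mass, 1.0, scenario)

    rng = _sub_rng(scenario.seed, "native")
    times = np.arange(0.0, scenario.gradient_min + 1e-9, scenario.native_scan_interval)
    base = scenario.apo_base_intensity
    spectra = []
    for i, t in enumerate(times):
        complex_totals = []
        for b in scenario.binders:
            complex_totals.append(base * b.ratio * float(_gauss(t, b.rt_apex, b.width)))
        drawn = sum(complex_totals)
        apo_total = max(base - drawn, 0.02 * base)  # ion current conservation
        peaks: list[tuple[float, float]] = []
        for z, mz, inten in _envelope(scenario.apo_mass, apo_total, scenario):
            peaks.append((mz, inten))
        for b, total in zip(scenario.binders, complex_totals):
            if total < 1e-3 * base:
                continue
            for z, mz, inten in _envelope(_complex_mass(scenario, b), total, scenario):
                peaks.append((mz, inten))
        peaks = _apply_noise(peaks, scenario, rng)
        mz_arr, int_arr = zip(*sorted(peaks))
        spectra.append(
            Spectrum(
                scan_id=f"native_scan={i + 1}",
                rt=float(t),
                ms_level=1,
                mz=np.array(mz_arr),
                intensity=np.array(int_arr),
            )
        )
    run = Run(
        spectra=spectra,
        metadata={"description": "synthetic native protein-infusion run",
                  "polarity": "positive", "mz_window": scenario.mz_window},
    )
    return run, build_ground_truth(scenario)


def _apply_noise(
    peaks: list[tuple[float, float]],
    scenario: ScreenScenario,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    out = []
    for mz, inten in peaks:
        jitter = rng.normal(0.0, scenario.mz_jitter_ppm * 1e-6 * mz)
        factor = (
            float(np.exp(rng.normal(0.0, scenario.noise_sigma)))
            if scenario.noise_sigma > 0
            else 1.0
        )
        out.append((mz + jitter, inten * factor))
    lo, hi = scenario.mz_window
    for _ in range(scenario.noise_peaks_per_scan):
        out.append(
            (float(rng.uniform(lo, hi)), float(rng.exponential(scenario.noise_floor)))
        )
    return out


def simulate_metabolomics_run(scenario: ScreenScenario) -> tuple[Run, GroundTruth]:
    """Generate the paired metabolomics LC-MS/MS (DDA) run."""
    rng = _sub_rng(scenario.seed, "metabolomics")
    times = np.arange(
        0.0, scenario.gradient_min + 1e-9, scenario.metabolomics_scan_interval
    )
    analytes = [
        {"mz": b.ligand_mass + PROTON_MASS, "rt": b.rt_apex, "width": b.width,
         "abundance": 1.0, "fragments": b.fragments, "label": f"binder_{k}"}
        for k, b in enumerate(scenario.binders)
    ] + [
        {"mz": d.mass + PROTON_MASS, "rt": d.rt_apex, "width": d.width,
         "abundance": d.abundance, "fragments": d.fragments, "label": f"decoy_{k}"}
        for k, d in enumerate(scenario.decoys)
    ]
    base = scenario.metabolite_base_intensity
    spectra = []
    scan_no = 0
    fired: dict[str, int] = {}
    for t in times:
        scan_no += 1
        peaks = []
        eligible = []
        for a in analytes:
            inten = base * a["abundance"] * float(_gauss(t, a["rt"], a["width"]))
            if inten > 1e-3 * base:
                peaks.append((a["mz"], inten))
                # DDA trigger near the apex, at most 3 MS2 per analyte.
                if inten > 0.5 * base * a["abundance"] and fired.get(a["label"], 0) < 3:
                    eligible.append((inten, a))
        if not peaks:
            peaks = [(scenario.mz_window[0], 0.0)]
        noisy = _apply_noise_metabolomics(peaks, scenario, rng)
        mz_arr, int_arr = zip(*sorted(noisy))
        spectra.append(
            Spectrum(
                scan_id=f"ms1_scan={scan_no}",
                rt=float(t),
                ms_level=1,
                mz=np.array(mz_arr),
                intensity=np.array(int_arr),
            )
        )
        # Up to two MS2 scans per duty cycle.
        eligible.sort(key=lambda e: -e[0])
        for inten, a in eligible[:2]:
            if not a["fragments"]:
                continue
            scan_no += 1
            fired[a["label"]] = fired.get(a["label"], 0) + 1
            fmz = np.array([f[0] for f in a["fragments"]])
            fint = np.array([f[1] for f in a["fragments"]]) * inten
            if scenario.noise_sigma > 0:
                fint = fint * np.exp(
                    rng.normal(0.0, scenario.noise_sigma, size=fint.size)
                )
            spectra.append(
                Spectrum(
                    scan_id=f"ms2_scan={scan_no}",
                    rt=float(t) + scenario.metabolomics_scan_interval * 0.25,
                    ms_level=2,
                    mz=fmz,
                    intensity=fint,
                    precursor=(float(a["mz"]), 1),
                )
            )
    run = Run(
        spectra=spectra,
        metadata={"description": "synthetic metabolomics DDA run",
                  "polarity": "positive"},
    )
    return run, build_ground_truth(scenario)


def _apply_noise_metabolomics(peaks, scenario, rng):
    out = []
    for mz, inten in peaks:
        jitter = rng.normal(0.0, scenario.mz_jitter_ppm * 1e-6 * mz)
        factor = (
            float(np.exp(rng.normal(0.0, scenario.noise_sigma)))
            if scenario.noise_sigma > 0
            else 1.0
        )
        out.append((mz + jitter, inten * factor))
    for _ in range(scenario.noise_peaks_per_scan):
        out.append(
            (float(rng.uniform(300.0, 2000.0)), float(rng.exponential(scenario.noise_floor)))
        )
    return out


def build_ground_truth(scenario: ScreenScenario) -> GroundTruth:
    """Planted-truth tables consistent with the scenario by construction."""
    prot_rows, met_rows, match_rows = [], [], []
    components: dict[str, set[str]] = {}
    for k, b in enumerate(scenario.binders):
        cmass = _complex_mass(scenario, b)
        prot_rows.append(
            {"label": f"binder_{k}", "complex_mass": cmass, "rt_apex": b.rt_apex,
             "stoichiometry": b.stoichiometry, "ratio": b.ratio}
        )
        met_rows.append(
            {"label": f"binder_{k}", "precursor_mz": b.ligand_mass + PROTON_MASS,
             "neutral_mass": b.ligand_mass, "rt_apex": b.rt_apex, "binder": True}
        )
        match_rows.append(
            {"label": f"binder_{k}", "complex_mass": cmass,
             "ligand_neutral_mass": b.ligand_mass, "rt_apex": b.rt_apex,
             "delta_mass": cmass - scenario.apo_mass,
             "stoichiometry": b.stoichiometry}
        )
        if b.family:
            components.setdefault(b.family, set()).add(f"binder_{k}")
    for k, d in enumerate(scenario.decoys):
        met_rows.append(
            {"label": f"decoy_{k}", "precursor_mz": d.mass + PROTON_MASS,
             "neutral_mass": d.mass, "rt_apex": d.rt_apex, "binder": False}
        )
        if d.family:
            components.setdefault(d.family, set()).add(f"decoy_{k}")
    return GroundTruth(
        protein_features=pd.DataFrame(prot_rows),
        metabolite_features=pd.DataFrame(met_rows),
        expected_matches=pd.DataFrame(match_rows),
        expected_components=components,
    )


def make_family_ladders(
    precursor_masses: list[float],
    n_fragments: int = 12,
    seed: int = 0,
    shifted_fraction: float = 0.5,
) -> list[tuple[tuple[float, float], ...]]:
    """Fragment ladders for a family of structural analogs.

    The first mass is the family prototype; its ladder is ``n_fragments``
    random rungs below the precursor.  Every other member keeps the
    low-mass rungs and shifts the top ``shifted_fraction`` of rungs by its
    precursor mass difference, mimicking a single residue substitution --
    exactly the pattern the modified cosine pairs via its two channels.
    """
    rng = _sub_rng(seed, "ladder")
    base_mass = precursor_masses[0]
    rungs = np.sort(rng.uniform(80.0, base_mass * 0.85, size=n_fragments))
    rel = rng.uniform(0.2, 1.0, size=n_fragments)
    split = int(n_fragments * (1.0 - shifted_fraction))
    ladders = []
    for m in precursor_masses:
        shift = m - base_mass
        frags = tuple(
            (float(rungs[i] + (shift if i >= split else 0.0)), float(rel[i]))
            for i in range(n_fragments)
        )
        ladders.append(frags)
    return ladders


def default_screen_scenario(
    n_binders: int = 30, n_decoys: int = 10, seed: int = 0
) -> ScreenScenario:
    """The default screen: 30 cyclodepsipeptide-like binders on a 10-min
    gradient eluting between 4 and 6 minutes, in analog families of 5,
    plus non-binding decoys with unrelated fragment ladders."""
    rng = _sub_rng(seed, "scenario")
    # Ligand masses in the Ahp-cyclodepsipeptide range, >= 10 Da apart so
    # neutral-mass traces stay resolved at the 5 Da trace window.
    masses = np.sort(rng.choice(np.arange(880.0, 1280.0, 10.0), size=n_binders, replace=False))
    masses = masses + rng.uniform(0.05, 0.95, size=n_binders)
    rts = np.linspace(4.0, 6.0, n_binders) + rng.uniform(-0.02, 0.02, size=n_binders)
    ratios = rng.uniform(0.1, 0.5, size=n_binders)
    family_size = 5
    binders = []
    k = 0
    while k < n_binders:
        members = list(range(k, min(k + family_size, n_binders)))
        fam = f"family_{k // family_size}"
        ladders = make_family_ladders(
            [float(masses[m] + PROTON_MASS) for m in members], seed=seed + k
        )
        for m, ladder in zip(members, ladders):
            binders.append(
                PlantedBinder(
                    ligand_mass=float(masses[m]),
                    rt_apex=float(rts[m]),
                    ratio=float(ratios[m]),
                    fragments=ladder,
                    family=fam,
                )
            )
        k += family_size
    decoy_masses = np.sort(
        rng.choice(np.arange(330.0, 870.0, 12.0), size=n_decoys, replace=False)
    ) + rng.uniform(0.05, 0.95, size=n_decoys)
    decoy_rts = rng.uniform(1.0, 9.0, size=n_decoys)
    decoys = []
    for i in range(n_decoys):
        ladder = make_family_ladders(
            [float(decoy_masses[i] + PROTON_MASS)], seed=seed + 1000 + i
        )[0]
        decoys.append(
            PlantedDecoy(
                mass=float(decoy_masses[i]),
                rt_apex=float(decoy_rts[i]),
                fragments=ladder,
                family=f"decoy_family_{i}",
            )
        )
    return ScreenScenario(binders=tuple(binders), decoys=tuple(decoys), seed=seed)


def proof_of_concept_scan(
    apo_mass: float = DEFAULT_APO_MASS,
    complex_mass: float = DEFAULT_APO_MASS + MOLASSAMIDE_MASS,
    ratio: float = 0.4,
    noiseless: bool = True,
    seed: int = 0,
) -> Spectrum:
    """One native-MS scan holding the apo and one complex envelope.

    Default masses reproduce the molassamide positive-control experiment:
    apo protein at 25232.6 Da and complex at 26195.1 Da.
    """
    scenario = ScreenScenario(
        apo_mass=apo_mass,
        binders=(
            PlantedBinder(
                ligand_mass=complex_mass - apo_mass,
                rt_apex=5.0,
                ratio=ratio,
                complex_mass=complex_mass,
            ),
        ),
        noise_sigma=0.0 if noiseless else ScreenScenario.noise_sigma,
        noise_peaks_per_scan=0 if noiseless else ScreenScenario.noise_peaks_per_scan,
        mz_jitter_ppm=0.0 if noiseless else ScreenScenario.mz_jitter_ppm,
        gradient_min=5.0,
        native_scan_interval=5.0,  # exactly two scans; we use the apex one
        seed=seed,
    )
    run, _ = simulate_native_run(scenario)
    apex = max(run.spectra, key=lambda s: s.rt)
    return apex


def simulate_titration(
    kd: float,
    rmax: float,
    concentrations,
    noise: float = 0.0,
    seed: int = 0,
    ligand_id: str = "ligand",
) -> TitrationSeries:
    """Titration series from the 1:1 saturation model with log-normal noise."""
    rng = _sub_rng(seed, "titration")
    c = np.asarray(concentrations, dtype=float)
    ratio = rmax * c / (kd + c)
    if noise > 0:
        ratio = ratio * np.exp(rng.normal(0.0, noise, size=c.size))
    return TitrationSeries.from_ratios(c, ratio, ligand_id=ligand_id)


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses=None,
    noise: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> DoseResponse:
    """Dose-response table from the 4PL model with multiplicative noise.

    The default design is eight half-log doses; replicates default to
    triplicate measurements.
    """
    if doses is None:
        doses = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
    doses = np.asarray(doses, dtype=float)
    rng = _sub_rng(seed, "dose_response")
    conc, resp, rep = [], [], []
    for r in range(replicates):
        y = bottom + (top - bottom) / (1.0 + (doses / ic50) ** hill)
        if noise > 0:
            y = y * (1.0 + rng.normal(0.0, noise, size=doses.size))
        conc.extend(doses)
        resp.extend(y)
        rep.extend([r] * doses.size)
    return DoseResponse(
        concentration=np.array(conc),
        response=np.array(resp),
        replicate=np.array(rep),
    )
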