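"""Charge-state deconvolution: recovery, assignment and trace building."""

import numpy as np
import pytest

from conftest import charge_envelope, make_scan
from nativemet.chem import mz_from_mass
from nativemet.deconvolution import (
    build_mass_traces,
    deconvolve_run,
    deconvolve_scan,
    detect_apo_depletion,
    extract_xic,
)
from nativemet.io import Run, Spectrum


def test_single_envelope_recovered():
    scan = make_scan([charge_envelope(25232.6, range(7, 11))])
    species = deconvolve_scan(scan)
    assert len(species) == 1
    sp = species[0]
    assert sp.neutral_mass == pytest.approx(25232.6, abs=0.5)
    assert set(sp.supporting_charges) == {7, 8, 9, 10}


def test_apo_plus_complex_mass_difference():
    """Apo and molassamide-complex envelopes give delta = 962.5 +- 0.1 Da."""
    scan = make_scan(
        [
            charge_envelope(25232.6, range(7, 11), total_intensity=1e6),
            charge_envelope(26195.1, range(7, 11), total_intensity=4e5),
        ]
    )
    species = deconvolve_scan(scan)
    assert len(species) == 2
    delta = species[1].neutral_mass - species[0].neutral_mass
    assert delta == pytest.approx(962.5, abs=0.1)
    assert species[0].neutral_mass == pytest.approx(25232.6, abs=0.5)


def test_empty_spectrum_empty_result():
    s = Spectrum("e", 1.0, 1, np.array([]), np.array([]))
    assert deconvolve_scan(s) == []


def test_single_charge_state_insufficient_support():
    s = Spectrum("one", 1.0, 1, np.array([2804.63]), np.array([1e6]))
    assert deconvolve_scan(s, min_charge_support=2) == []


def test_invalid_charge_range():
    s = Spectrum("x", 1.0, 1, np.array([1000.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        deconvolve_scan(s, charge_range=(10, 5))


def test_round_trip_property_over_random_masses(rng):
    """Any mass in [10, 60] kDa with >= 3 supporting charges from [5, 25]
    is recovered within twice the intra-series tolerance."""
    n_fail = 0
    for _ in range(100):
        mass = float(rng.uniform(1.0e4, 6.0e4))
        n_z = int(rng.integers(3, 8))
        z_lo = int(rng.integers(5, 25 - n_z))
        charges = range(z_lo, z_lo + n_z)
        scan = make_scan(
            [charge_envelope(mass, charges, charge_mean=z_lo + n_z / 2, charge_sigma=2.0)]
        )
        species = deconvolve_scan(scan)
        tol = 2 * max(0.05, 10e-6 * mass)
        if not (len(species) >= 1 and abs(species[0].neutral_mass - mass) <= tol):
            n_fail += 1
    assert n_fail == 0


def test_permutation_invariance(rng):
    scan = make_scan(
        [
            charge_envelope(25232.6, range(7, 11)),
            charge_envelope(26420.0, range(7, 11), total_intensity=3e5),
        ]
    )
    perm = rng.permutation(scan.n_peaks)
    shuffled = Spectrum("p", scan.rt, 1, scan.mz[perm], scan.intensity[perm])
    a = deconvolve_scan(scan)
    b = deconvolve_scan(shuffled)
    assert [round(x.neutral_mass, 6) for x in a] == [round(x.neutral_mass, 6) for x in b]


def test_distinct_species_never_merged():
    """Species 12 Da apart (far beyond the intra-series tolerance) stay split."""
    scan = make_scan(
        [
            charge_envelope(25232.6, range(7, 11)),
            charge_envelope(25244.6, range(7, 11), total_intensity=8e5),
        ]
    )
    species = deconvolve_scan(scan)
    masses = sorted(sp.neutral_mass for sp in species)
    assert len(masses) == 2
    assert masses[1] - masses[0] == pytest.approx(12.0, abs=0.3)


def test_intensity_conservation():
    scan = make_scan([charge_envelope(25232.6, range(7, 11), total_intensity=1e6)])
    species = deconvolve_scan(scan)
    assert species[0].total_intensity <= scan.intensity.sum() + 1e-6
    assert species[0].total_intensity == pytest.approx(1e6, rel=1e-9)


def _run_with_species(masses_per_scan, dt=0.1):
    spectra = []
    for i, masses in enumerate(masses_per_scan):
        envs = [charge_envelope(m, range(7, 11)) for m in masses]
        if envs:
            s = make_scan(envs, rt=i * dt)
            s.scan_id = f"scan={i}"
        else:
            s = Spectrum(f"scan={i}", i * dt, 1, np.array([2600.0]), np.array([1.0]))
        spectra.append(s)
    return Run(spectra=spectra)


def test_mass_trace_built_over_scans():
    run = _run_with_species([[25232.6]] * 10)
    traces = build_mass_traces(run, window=5.0, min_scans=3)
    assert len(traces) == 1
    assert traces[0].center_mass == pytest.approx(25232.6, abs=0.5)
    assert traces[0].n_points == 10


def test_mass_traces_separated_beyond_window():
    run = _run_with_species([[25232.6, 25244.6]] * 5)
    traces = build_mass_traces(run, window=5.0, min_scans=3)
    assert len(traces) == 2


def test_short_trace_discarded():
    run = _run_with_species([[25232.6]] * 2 + [[]] * 8)
    assert build_mass_traces(run, window=5.0, min_scans=3) == []


def test_extract_xic_zero_and_exact():
    run = _run_with_species([[25232.6]] * 5)
    rt, xic = extract_xic(run, 25232.6, window=5.0)
    assert np.all(xic > 0)
    rt, none_xic = extract_xic(run, 40000.0, window=5.0)
    assert np.all(none_xic == 0)


def test_apo_depletion_detection():
    rt = np.arange(0, 10, 0.02)
    base = np.full_like(rt, 1.0e6)
    dip = 1.0e6 * 0.6 * np.exp(-0.5 * ((rt - 5.0) / 0.05) ** 2)
    events = detect_apo_depletion(rt, base - dip, min_depth_frac=0.3)
    assert len(events) == 1
    assert events[0][0] == pytest.approx(5.0, abs=0.05)
    assert events[0][1] == pytest.approx(0.6, abs=0.1)


def test_apo_depletion_flat_trace():
    rt = np.arange(0, 10, 0.02)
    assert detect_apo_depletion(rt, np.full_like(rt, 5.0e5)) == []
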