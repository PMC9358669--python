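"""Peak detection, metabolite feature building and co-elution scoring."""

import numpy as np
import pytest

from conftest import gaussian_trace, simple_feature
from nativemet.features import (
    build_metabolite_features,
    coelution_correlation,
    detect_peaks,
)
from nativemet.io import Run, Spectrum


def test_single_gaussian_peak():
    rt, inten = gaussian_trace(5.5, sigma=0.05, height=1e6)
    feats = detect_peaks(rt, inten, min_height=1e4)
    assert len(feats) == 1
    f = feats[0]
    assert f.rt_apex == pytest.approx(5.5, abs=0.02)
    assert f.rt_start < f.rt_apex < f.rt_end
    assert f.apex_intensity == pytest.approx(1e6, rel=0.05)
    # analytic area of the Gaussian: height * sigma * sqrt(2 pi)
    assert f.area == pytest.approx(1e6 * 0.05 * np.sqrt(2 * np.pi), rel=0.05)


def test_two_separated_gaussians():
    rt, a = gaussian_trace(4.0, sigma=0.05)
    _, b = gaussian_trace(5.0, sigma=0.05)
    feats = detect_peaks(rt, a + b, min_height=1e4)
    assert len(feats) == 2
    assert [round(f.rt_apex, 1) for f in feats] == [4.0, 5.0]


def test_flat_trace_no_features():
    rt = np.arange(0, 10, 0.01)
    assert detect_peaks(rt, np.zeros_like(rt)) == []
    assert detect_peaks(rt, np.full_like(rt, 3.0)) == []


def test_superposition_equals_union():
    """Well-separated peaks detected jointly match those detected alone."""
    rt, a = gaussian_trace(3.0, sigma=0.05)
    _, b = gaussian_trace(7.0, sigma=0.08, height=5e5)
    solo = detect_peaks(rt, a, min_height=1e4) + detect_peaks(rt, b, min_height=1e4)
    joint = detect_peaks(rt, a + b, min_height=1e4)
    assert len(joint) == len(solo) == 2
    for fs, fj in zip(sorted(solo, key=lambda f: f.rt_apex), joint):
        assert fj.rt_apex == pytest.approx(fs.rt_apex, abs=0.01)
        assert fj.area == pytest.approx(fs.area, rel=0.02)


def test_area_invariant_under_resampling():
    rt1, i1 = gaussian_trace(5.0, sigma=0.1, dt=0.01)
    rt2, i2 = gaussian_trace(5.0, sigma=0.1, dt=0.003)
    a1 = detect_peaks(rt1, i1, min_height=1e3)[0].area
    a2 = detect_peaks(rt2, i2, min_height=1e3)[0].area
    assert a1 == pytest.approx(a2, rel=0.01)


def _metab_run():
    times = np.arange(5.0, 6.0, 0.02)
    spectra = []
    for i, t in enumerate(times):
        inten = 1e6 * np.exp(-0.5 * ((t - 5.5) / 0.05) ** 2)
        spectra.append(
            Spectrum(
                f"ms1={i}", float(t), 1,
                np.array([400.0, 1186.6400]),
                np.array([2e5, max(inten, 1.0)]),
            )
        )
    spectra.append(
        Spectrum("ms2=apex", 5.51, 2, np.array([100.0, 500.0]), np.array([1.0, 2.0]),
                 precursor=(1186.6401, 1))
    )
    spectra.append(
        Spectrum("ms2=late", 5.95, 2, np.array([100.0]), np.array([1.0]),
                 precursor=(1186.6401, 1))
    )
    return Run(spectra=spectra)


def test_metabolite_features_and_msms_linking():
    feats, spectra = build_metabolite_features(_metab_run(), mz_tol=10.0, min_height=1e4)
    target = [f for f in feats if abs(f.mass_value - 1186.64) < 0.01]
    assert len(target) == 1
    f = target[0]
    assert f.rt_apex == pytest.approx(5.5, abs=0.03)
    # the apex MS2 is linked; the one outside the peak window is not
    assert f.msms_scan_ids == ["ms2=apex"]
    assert "ms2=late" in spectra


def test_two_coeluting_mz_give_two_features():
    times = np.arange(5.0, 6.0, 0.02)
    spectra = [
        Spectrum(
            f"s{i}", float(t), 1,
            np.array([800.0, 900.0]),
            np.array([1e6 * np.exp(-0.5 * ((t - 5.5) / 0.05) ** 2) + 1.0] * 2),
        )
        for i, t in enumerate(times)
    ]
    feats, _ = build_metabolite_features(Run(spectra=spectra), min_height=1e4)
    assert len(feats) == 2
    assert sorted(round(f.mass_value) for f in feats) == [800, 900]


def test_coelution_identical_and_negated():
    f1 = simple_feature("a", 1000.0, 5.0)
    assert coelution_correlation(f1, f1) == pytest.approx(1.0)
    f2 = simple_feature("b", 1001.0, 5.0)
    f2.trace_intensity = -f2.trace_intensity + f2.trace_intensity.max()
    assert coelution_correlation(f1, f2) == pytest.approx(-1.0, abs=1e-9)


def test_coelution_offset_gaussians_matches_quadrature_oracle():
    """Offset-by-3-sigma Gaussians: score equals an independent dense-grid
    Pearson computation."""
    sigma = 0.05
    f1 = simple_feature("a", 1000.0, 5.0, sigma=sigma)
    f2 = simple_feature("b", 1001.0, 5.0 + 3 * sigma, sigma=sigma)
    got = coelution_correlation(f1, f2)
    # oracle: same definition computed independently on a dense union grid
    lo = max(f1.rt_start, f2.rt_start)
    hi = min(f1.rt_end, f2.rt_end)
    grid = np.linspace(lo, hi, 20001)
    a = 1e6 * np.exp(-0.5 * ((grid - 5.0) / sigma) ** 2)
    b = 1e6 * np.exp(-0.5 * ((grid - 5.0 - 3 * sigma) / sigma) ** 2)
    oracle = np.corrcoef(a, b)[0, 1]
    assert got == pytest.approx(oracle, abs=0.02)


def test_coelution_no_overlap_is_nan():
    f1 = simple_feature("a", 1000.0, 2.0)
    f2 = simple_feature("b", 1001.0, 8.0)
    assert np.isnan(coelution_correlation(f1, f2))
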