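"""Shared fixtures: synthetic envelopes, traces and features."""

from __future__ import annotations

import numpy as np
import pytest

from nativemet.chem import mz_from_mass
from nativemet.features import Feature
from nativemet.io import Spectrum


def charge_envelope(
    mass: float,
    charges,
    total_intensity: float = 1.0e6,
    charge_mean: float = 8.5,
    charge_sigma: float = 1.2,
) -> list[tuple[float, float]]:
    """Centroided (m/z, intensity) peaks of one species' charge envelope."""
    zs = np.asarray(list(charges))
    w = np.exp(-0.5 * ((zs - charge_mean) / charge_sigma) ** 2)
    w = w / w.sum()
    return [
        (mz_from_mass(mass, int(z)), float(total_intensity * wi))
        for z, wi in zip(zs, w)
    ]


def make_scan(peak_sets: list[list[tuple[float, float]]], rt: float = 5.0) -> Spectrum:
    """One MS1 scan from several envelopes' peak lists."""
    peaks = sorted(p for ps in peak_sets for p in ps)
    mz, intensity = zip(*peaks)
    return Spectrum(
        scan_id="fixture", rt=rt, ms_level=1, mz=np.array(mz), intensity=np.array(intensity)
    )


def gaussian_trace(
    apex_rt: float,
    sigma: float = 0.05,
    height: float = 1.0e6,
    rt_range: tuple[float, float] = (0.0, 10.0),
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    rt = np.arange(rt_range[0], rt_range[1] + 1e-9, dt)
    return rt, height * np.exp(-0.5 * ((rt - apex_rt) / sigma) ** 2)


def simple_feature(
    fid: str,
    mass: float,
    rt_apex: float,
    kind: str = "metabolite",
    sigma: float = 0.05,
    height: float = 1.0e6,
    area: float | None = None,
    persistent: bool = False,
) -> Feature:
    rt, inten = gaussian_trace(rt_apex, sigma=sigma, height=height,
                               rt_range=(rt_apex - 4 * sigma, rt_apex + 4 * sigma))
    return Feature(
        id=fid,
        kind=kind,
        mass_value=mass,
        rt_apex=rt_apex,
        rt_start=float(rt[0]),
        rt_end=float(rt[-1]),
        apex_intensity=height,
        area=area if area is not None else float(np.trapezoid(inten, rt)),
        trace_rt=rt,
        trace_intensity=inten,
        persistent=persistent,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
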