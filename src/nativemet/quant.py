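"""Binding quantification: titration curves, detection-limit summaries,
and four-parameter-logistic (4PL) IC50 fits.

Titration of a ligand against constant protein is summarized as the
bound/unbound intensity ratio versus ligand concentration and fitted with
a 1:1 hyperbolic saturation model

    ratio(c) = Rmax * c / (Kd + c),

whose midpoint is an *apparent* dissociation constant: electrospray
response factors of apo and complex are unknown, so the gas-phase ratio is
taken as proportional to the solution ratio but not calibrated.

Enzyme-inhibition dose-response data are fitted with the standard 4PL

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill),

reporting the curve midpoint (relative IC50) and standard errors from the
local curvature of the least-squares solution.  Both fits use three
perturbed initializations (deterministic) and keep the best residual sum
of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "DoseResponse",
    "IC50Fit",
    "fit_titration",
    "summarize_dilution",
    "fit_ic50",
    "fold_change",
]


class QuantError(ValueError):
    """Raised for inputs on which no fit is defined."""


@dataclass
class TitrationSeries:
    """Bound/unbound ratio versus ligand concentration for one ligand."""

    concentration: np.ndarray
    bound_area: np.ndarray
    apo_area: np.ndarray
    ligand_id: str = ""

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.bound_area = np.asarray(self.bound_area, dtype=float)
        self.apo_area = np.asarray(self.apo_area, dtype=float)
        if np.any(self.concentration < 0):
            raise QuantError("negative concentration")
        if np.any(self.bound_area < 0) or np.any(self.apo_area < 0):
            raise QuantError("negative peak area")
        order = np.argsort(self.concentration)
        self.concentration = self.concentration[order]
        self.bound_area = self.bound_area[order]
        self.apo_area = self.apo_area[order]

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.apo_area > 0, self.bound_area / self.apo_area, np.inf
            )

    @classmethod
    def from_ratios(
        cls, concentration, ratio, ligand_id: str = ""
    ) -> "TitrationSeries":
        ratio = np.asarray(ratio, dtype=float)
        return cls(
            concentration=np.asarray(concentration, dtype=float),
            bound_area=ratio,
            apo_area=np.ones_like(ratio),
            ligand_id=ligand_id,
        )


@dataclass
class BindingFit:
    kd_apparent: float
    rmax: float
    rss: float
    converged: bool

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.rmax * c / (self.kd_apparent + c)


def _multistart_curve_fit(model, x, y, p0, bounds, n_starts=3):
    """Deterministic multi-start least squares; best RSS wins."""
    rng = np.random.default_rng(0)
    best = None
    starts = [np.asarray(p0, dtype=float)]
    for _ in range(n_starts - 1):
        starts.append(starts[0] * rng.uniform(0.5, 2.0, size=len(p0)))
    for start in starts:
        start = np.clip(start, bounds[0], bounds[1])
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    return best


def fit_titration(series: TitrationSeries) -> BindingFit:
    """Fit the 1:1 hyperbolic saturation model to a titration series.

    Initialization: Rmax = max observed ratio, Kd = concentration at
    half-maximal observed ratio.  The fitted curve passes through (0, 0)
    by construction of the model.
    """
    c = series.concentration
    r = series.ratio
    finite = np.isfinite(r)
    c, r = c[finite], r[finite]
    if np.unique(c).size < 3:
        raise QuantError("need at least 3 distinct concentrations")
    if np.all(r <= 0):
        raise QuantError("no binding signal: all ratios are zero")

    def model(x, kd, rmax):
        return rmax * x / (kd + x)

    rmax0 = float(np.max(r))
    half = rmax0 / 2.0
    above = c[r >= half]
    kd0 = float(above[0]) if above.size else float(np.median(c[c > 0]))
    kd0 = max(kd0, 1e-12)
    best = _multistart_curve_fit(
        model, c, r, [kd0, rmax0], ([1e-12, 1e-12], [np.inf, np.inf])
    )
    if best is None:
        return BindingFit(kd_apparent=kd0, rmax=rmax0, rss=math.inf, converged=False)
    popt, _, rss = best
    return BindingFit(
        kd_apparent=float(popt[0]), rmax=float(popt[1]), rss=rss, converged=True
    )


@dataclass
class DilutionSummary:
    slope: float
    intercept: float
    r_squared: float
    lod_low: float | None  # largest tested concentration with no signal
    lod_high: float | None  # smallest tested concentration with signal
    note: str


def summarize_dilution(
    concentration,
    area,
    blank_mean: float = 0.0,
    blank_sd: float = 0.0,
) -> DilutionSummary:
    """Summarize a serial-dilution calibration series.

    A concentration "has signal" when its area exceeds blank_mean + 3 *
    blank_sd.  The detection limit is bracketed by the largest tested
    concentration without signal and the smallest with signal; the linear
    range (all with-signal points) is summarized by an ordinary
    least-squares slope/intercept/R^2.
    """
    from scipy.stats import linregress

    c = np.asarray(concentration, dtype=float)
    a = np.asarray(area, dtype=float)
    order = np.argsort(c)
    c, a = c[order], a[order]
    threshold = blank_mean + 3.0 * blank_sd
    has_signal = a > threshold
    if has_signal.all():
        lod_low, lod_high = None, float(c[0])
        note = f"LOD < lowest tested concentration ({c[0]:g})"
    elif not has_signal.any():
        lod_low, lod_high = float(c[-1]), None
        note = f"LOD > highest tested concentration ({c[-1]:g})"
    else:
        first_signal = int(np.argmax(has_signal))
        blank_below = c[:first_signal][~has_signal[:first_signal]]
        lod_high = float(c[first_signal])
        lod_low = float(blank_below[-1]) if blank_below.size else None
        note = f"LOD between {lod_low:g} and {lod_high:g}" if lod_low is not None else (
            f"LOD <= {lod_high:g}"
        )
    sel = has_signal
    if sel.sum() >= 2 and np.unique(c[sel]).size >= 2:
        res = linregress(c[sel], a[sel])
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        slope = intercept = r2 = float("nan")
    return DilutionSummary(slope, intercept, r2, lod_low, lod_high, note)


@dataclass
class DoseResponse:
    """Inhibitor concentration vs measured velocity/signal, with replicates."""

    concentration: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
        if np.unique(self.concentration[self.concentration > 0]).size < 4:
            raise QuantError(
                "need at least 4 distinct nonzero concentrations for a dose-response fit"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponse":
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            concentration=df["concentration"].to_numpy(),
            response=df["response"].to_numpy(),
            replicate=rep,
        )


@dataclass
class IC50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float
    stderr: dict = field(default_factory=dict)
    rss: float = math.nan
    converged: bool = False
    no_inhibition: bool = False


def _four_pl(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(d: DoseResponse, constrain_bottom: bool = False) -> IC50Fit:
    """Fit the 4PL model to a dose-response table.

    Initialization: top = max response, bottom = min response, ic50 = dose
    nearest the mid-response, hill = 1.  ``constrain_bottom=True`` pins the
    lower asymptote at zero.  A response that does not decrease overall is
    flagged ``no_inhibition`` rather than fitted.
    """
    sel = d.concentration > 0
    c = d.concentration[sel]
    y = d.response[sel]
    order = np.argsort(c)
    c, y = c[order], y[order]

    # Overall decrease check on per-dose means of the low vs high tercile.
    doses = np.unique(c)
    means = np.array([y[c == dd].mean() for dd in doses])
    k = max(1, len(doses) // 3)
    low, high = means[:k].mean(), means[-k:].mean()
    spread = float(means.max() - means.min())
    if spread <= 0 or (low - high) < 0.1 * spread:
        return IC50Fit(
            ic50=math.nan,
            hill=math.nan,
            top=float(means.max()),
            bottom=float(means.min()),
            no_inhibition=True,
        )

    top0 = float(y.max())
    bottom0 = float(y.min())
    mid = (top0 + bottom0) / 2.0
    ic50_0 = float(doses[np.argmin(np.abs(means - mid))])

    if constrain_bottom:
        def model(x, top, ic50, hill):
            return _four_pl(x, 0.0, top, ic50, hill)

        p0 = [top0, ic50_0, 1.0]
        bounds = ([0, 1e-12, 0.1], [np.inf, np.inf, 10.0])
        names = ["top", "ic50", "hill"]
    else:
        def model(x, bottom, top, ic50, hill):
            return _four_pl(x, bottom, top, ic50, hill)

        p0 = [bottom0, top0, ic50_0, 1.0]
        bounds = ([-np.inf, 0, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0])
        names = ["bottom", "top", "ic50", "hill"]

    best = _multistart_curve_fit(model, c, y, p0, bounds)
    if best is None:
        return IC50Fit(
            ic50=ic50_0, hill=1.0, top=top0, bottom=bottom0, converged=False
        )
    popt, pcov, rss = best
    params = dict(zip(names, map(float, popt)))
    with np.errstate(invalid="ignore"):
        errs = np.sqrt(np.diag(pcov)) if pcov is not None else [math.nan] * len(popt)
    stderr = dict(zip(names, map(float, errs)))
    fit = IC50Fit(
        ic50=params["ic50"],
        hill=params["hill"],
        top=params["top"],
        bottom=params.get("bottom", 0.0),
        stderr=stderr,
        rss=rss,
        converged=True,
    )
    if not (fit.bottom < fit.top):
        fit.converged = False
    return fit


def fold_change(ic50_a: float, ic50_b: float) -> float:
    """Potency fold-difference ic50_a / ic50_b.

    With the "n-fold increase in potency" convention the less potent
    (larger) IC50 goes first.
    """
    if ic50_a <= 0 or ic50_b <= 0:
        raise QuantError("IC50 values must be positive for a fold change")
    return ic50_a / ic50_b
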