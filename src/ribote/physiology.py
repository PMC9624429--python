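"""Translation-physiology computations.

Total ribosome number from bulk measurements, polysome-profile (A254 sucrose
gradient trace) quantification — tail-baseline subtraction, exponential
background removal, per-peak trapezoidal areas, two-Gaussian decomposition of
the 70S peak — and ribosome elongation-rate estimation from a lacZ induction
time series.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PhysiologyParams",
    "PolysomeTrace",
    "PeakQuantification",
    "ribosome_total",
    "correct_baseline",
    "fit_background",
    "quantify_peaks",
    "split_70s",
    "elongation_rate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhysiologyParams:
    """Inputs of the total-ribosome computation.

    Vc: cell volume (m^3); Cp: protein concentration (g/m^3); RPR:
    RNA-to-protein mass ratio; fr: fractional mass of rRNA among total RNA;
    mr: rRNA mass per ribosome (g).
    """

    Vc: float
    Cp: float
    RPR: float
    fr: float
    mr: float

    def __post_init__(self) -> None:
        for name in ("Vc", "Cp", "mr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("RPR", "fr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fr > 1:
            raise ValueError("fr is a mass fraction and must be <= 1")


def ribosome_total(params: PhysiologyParams) -> float:
    """Ribosomes per average cell: Rt = Vc * Cp * RPR * fr / mr."""
    return params.Vc * params.Cp * params.RPR * params.fr / params.mr


@dataclass
class PolysomeTrace:
    """An A254 absorbance trace along a sucrose gradient."""

    positions: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance must have equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakQuantification:
    baseline: float = 0.0
    background_amplitude: float = 0.0
    background_decay: float = 0.0
    areas: dict[str, float] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    split_70s: dict | None = None


def correct_baseline(trace: PolysomeTrace, n_tail: int = 50) -> PolysomeTrace:
    """Subtract the mean of the final ``n_tail`` readings (no RNA there).

    Negative values after subtraction are retained (and logged), not
    clipped.
    """
    if n_tail < 1 or n_tail > len(trace.absorbance):
        raise ValueError("n_tail must be within the trace length")
    baseline = float(trace.absorbance[-n_tail:].mean())
    corrected = trace.absorbance - baseline
    n_neg = int((corrected < 0).sum())
    if n_neg:
        log.info("correct_baseline: %d negative readings retained", n_neg)
    meta = dict(trace.metadata, baseline=baseline)
    return PolysomeTrace(trace.positions, corrected, meta)


def fit_background(
    trace: PolysomeTrace, fit_window: tuple[float, float]
) -> tuple[PolysomeTrace, float, float]:
    """Fit a*exp(-k*x) over the leading non-ribosomal region and subtract it.

    The window should cover the descending flank of the free-nucleotide/tRNA
    peak; the fitted exponential is subtracted over the whole trace.
    Returns (corrected trace, amplitude, decay).
    """
    x, y = trace.positions, trace.absorbance
    lo, hi = fit_window
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise ValueError("fit window covers fewer than 3 points")
    xw, yw = x[mask], y[mask]
    if np.allclose(yw, 0.0):
        return trace, 0.0, 0.0

    def model(x, a, k):
        return a * np.exp(-k * x)

    a0 = max(float(yw[0]), 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, xw, yw, p0=(a0, 1.0), maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"exponential background fit did not converge: {err}")
    a, k = float(popt[0]), float(popt[1])
    resid = yw - model(xw, a, k)
    rms = float(np.sqrt(np.mean(resid**2)))
    log.info("fit_background: a=%.4g k=%.4g residual RMS=%.3g", a, k, rms)
    meta = dict(trace.metadata, background_amplitude=a, background_decay=k,
                background_rms=rms)
    return PolysomeTrace(x, y - model(x, a, k), meta), a, k


def quantify_peaks(
    trace: PolysomeTrace, peak_windows: dict[str, tuple[float, float]]
) -> PeakQuantification:
    """Trapezoidal area under each named window; fractions normalized.

    Windows must not overlap; the trace should already be baseline- and
    background-corrected.
    """
    spans = sorted(peak_windows.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise ValueError("peak windows overlap")
    x, y = trace.positions, trace.absorbance
    areas = {}
    for name, (lo, hi) in peak_windows.items():
        mask = (x >= lo) & (x <= hi)
        areas[name] = float(np.trapezoid(y[mask], x[mask])) if mask.sum() > 1 else 0.0
    total = sum(areas.values())
    fractions = {n: (a / total if total > 0 else float("nan")) for n, a in areas.items()}
    quant = PeakQuantification(
        baseline=float(trace.metadata.get("baseline", 0.0)),
        background_amplitude=float(trace.metadata.get("background_amplitude", 0.0)),
        background_decay=float(trace.metadata.get("background_decay", 0.0)),
        areas=areas,
        fractions=fractions,
    )
    return quant


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    g1 = a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    g2 = a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return g1 + g2


def split_70s(
    trace: PolysomeTrace, window: tuple[float, float], resolution: float | None = None
) -> dict:
    """Decompose the overlapped 70S peak into two Gaussians.

    Free (no mRNA) and mRNA-bound 70S co-sediment; under high potassium the
    free particles shift to lower density, so the lower-position Gaussian is
    assigned 'free' and the higher-position one 'bound'.  If the fitted
    means coincide within ``resolution`` (default: window width / 20) a
    single-peak fallback is reported with a warning.
    """
    x, y = trace.positions, trace.absorbance
    lo, hi = window
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 7:
        raise ValueError("window covers too few points for a two-Gaussian fit")
    xw, yw = x[mask], y[mask]
    width = hi - lo
    resolution = resolution if resolution is not None else width / 20
    area0 = max(float(np.trapezoid(yw, xw)), 1e-12)
    p0 = (area0 / 2, lo + width / 3, width / 8, area0 / 2, lo + 2 * width / 3, width / 8)
    bounds = (
        [0, lo, 1e-6, 0, lo, 1e-6],
        [np.inf, hi, width, np.inf, hi, width],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_two_gauss, xw, yw, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"two-Gaussian fit did not converge: {err}")
    a1, m1, s1, a2, m2, s2 = (float(v) for v in popt)
    if abs(m1 - m2) < resolution:
        warnings.warn("70S split collapsed to coincident means; single-peak fallback")
        return {
            "collapsed": True,
            "mean": (m1 + m2) / 2,
            "area": a1 + a2,
        }
    first, second = sorted([(m1, s1, a1), (m2, s2, a2)])
    return {
        "collapsed": False,
        "free": {"mean": first[0], "sd": first[1], "area": first[2]},
        "bound": {"mean": second[0], "sd": second[1], "area": second[2]},
        "free_fraction": first[2] / (first[2] + second[2]),
    }


def elongation_rate(
    series: tuple[np.ndarray, np.ndarray],
    lacz_length_aa: int = 1024,
    correction_s: float = 10.0,
    fit_space: str = "sqrt",
    onset_fraction: float = 0.02,
) -> dict:
    """Elongation rate (aa/s) from an accumulated lacZ induction series.

    The integrated product signal grows quadratically once the first
    complete enzymes appear, so sqrt(signal) is linear in time; the fitted
    line's x-intercept is the measured delay T, and the rate is
    lacz_length_aa / (T - correction_s), the correction removing the
    non-elongation portion of the assay delay.  ``fit_space='raw'`` fits the
    signal itself instead (legacy option).
    """
    t = np.asarray(series[0], dtype=float)
    y = np.asarray(series[1], dtype=float)
    if lacz_length_aa <= 0:
        raise ValueError("lacz_length_aa must be > 0")
    peak = y.max()
    if peak <= 0:
        raise ValueError("series carries no signal")
    post = y > onset_fraction * peak
    if post.sum() < 5:
        raise ValueError("need >= 5 post-onset points for the linear fit")
    tf, yf = t[post], y[post]
    if fit_space == "sqrt":
        yy = np.sqrt(np.clip(yf, 0, None))
    elif fit_space == "raw":
        yy = yf
    else:
        raise ValueError(f"unknown fit_space {fit_space!r}")
    slope, intercept = np.polyfit(tf, yy, 1)
    if slope <= 0:
        raise ValueError("non-increasing signal; cannot infer a delay")
    delay = -intercept / slope
    if delay <= correction_s:
        raise ValueError(
            f"measured delay {delay:.3g} s <= correction {correction_s} s (nonphysical)"
        )
    rate = lacz_length_aa / (delay - correction_s)
    return {
        "rate_aa_per_s": float(rate),
        "measured_delay_s": float(delay),
        "corrected_delay_s": float(delay - correction_s),
        "slope": float(slope),
        "n_points": int(post.sum()),
    }
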