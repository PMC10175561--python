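"""Arrhenius-profile analysis of heat-ramp currents.

The headline procedure of the package: the heat-evoked current magnitude at
the holding potential is plotted on a natural-log scale against the
reciprocal of the absolute temperature (the Arrhenius profile). Exponential
temperature dependences appear as straight segments; a heat-gated channel
shows a shallow leak-dominated baseline segment and a steep activation
segment. The activation threshold is the temperature at the point of
intersection between linear fits to the baseline and to the steepest
component of the profile. The steep-segment slope also yields the apparent
activation energy Ea = -slope * R and hence the temperature coefficient

    Q10 = exp(Ea * 10 / (R * T_ref * (T_ref + 10)))        (temperatures in K).

Two complementary summaries are provided: the half-maximal activation
temperature (where the leak-subtracted current reaches 50% of its ramp
maximum) and the current at a probe temperature standardized by the same
cell's capsaicin response.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import (DetectionConfig, KELVIN_OFFSET, R_GAS, celsius_to_kelvin,
                     kelvin_to_celsius)
from .exceptions import (DomainError, ExtrapolationError, InsufficientDataError,
                         MissingReferenceError, NoActivationError,
                         NoIntersectionError, NoSteepComponentError)
from .synthetic import TemperatureTrace

__all__ = [
    "ArrheniusProfile",
    "SegmentFit",
    "ThresholdResult",
    "to_arrhenius",
    "detect_threshold",
    "compute_q10",
    "half_max_activation_temp",
    "current_at_temperature",
    "analyze_trace",
]


@dataclass(frozen=True)
class ArrheniusProfile:
    """Log current magnitude vs reciprocal absolute temperature.

    Samples are ordered by ascending 1/T (descending temperature). Samples
    with non-positive current magnitude fall outside the ln domain; they are
    excluded and counted in ``n_dropped``.
    """

    inv_temp_K: np.ndarray
    log_current: np.ndarray
    source_index: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.inv_temp_K)

    @property
    def temp_C(self) -> np.ndarray:
        return kelvin_to_celsius(1.0 / self.inv_temp_K)


@dataclass(frozen=True)
class SegmentFit:
    """Least-squares line over a contiguous index range of the profile."""

    slope: float          # K, in 1/T coordinates
    intercept: float
    index_range: tuple[int, int]   # [start, end) over the profile
    r2: float

    def predict(self, inv_temp_K):
        return self.intercept + self.slope * np.asarray(inv_temp_K)


@dataclass
class ThresholdResult:
    """Threshold detection output plus downstream summaries and diagnostics."""

    threshold_C: float
    baseline: SegmentFit
    steep: SegmentFit
    q10: Optional[float] = None
    t_half_act_C: Optional[float] = None
    i_at_probe_norm: Optional[float] = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def to_arrhenius(trace: TemperatureTrace, min_points: int = 1) -> ArrheniusProfile:
    """Build the Arrhenius profile of a trace.

    x_i = 1/(temp_C_i + 273.15), y_i = ln|current_i|; zero-current samples
    are dropped (and counted) because ln is undefined there. The result is
    sorted by ascending 1/T regardless of ramp direction.
    """
    mag = np.abs(trace.current_nA)
    usable = mag > 0
    n_dropped = int((~usable).sum())
    if usable.sum() < max(min_points, 1):
        raise InsufficientDataError(
            f"only {int(usable.sum())} samples with |I| > 0 (need {min_points})"
        )
    idx = np.nonzero(usable)[0]
    x = 1.0 / celsius_to_kelvin(trace.temp_C[idx])
    y = np.log(mag[idx])
    order = np.argsort(x, kind="stable")
    return ArrheniusProfile(inv_temp_K=x[order], log_current=y[order],
                            source_index=idx[order], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------

def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Centered least squares; returns (slope, intercept, r2).

    r2 is defined as 1 for an exact fit even when y is constant (ss_tot = 0),
    so noiseless horizontal baselines are not rejected.
    """
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DomainError("degenerate x values in segment fit")
    slope = float(dx @ dy) / sxx
    intercept = ym - slope * xm
    resid = dy - slope * dx
    ss_res = float(resid @ resid)
    ss_tot = float(dy @ dy)
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def _window_stats(x: np.ndarray, y: np.ndarray, w: int):
    """Slope and r2 of every length-w sliding window, vectorized."""
    n = len(x)
    m = n - w + 1
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    i = np.arange(m)
    sx = c1[i + w] - c1[i]
    sxx = c2[i + w] - c2[i]
    sy = cy[i + w] - cy[i]
    syy = cy2[i + w] - cy2[i]
    sxy = cxy[i + w] - cxy[i]
    vxx = sxx - sx * sx / w
    vyy = syy - sy * sy / w
    vxy = sxy - sx * sy / w
    slope = vxy / vxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(vyy > 0, vxy * vxy / (vxx * vyy), 1.0)
    # cumulative sums lose precision on long flat stretches; clamp
    return slope, np.clip(r2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# threshold detection
# ---------------------------------------------------------------------------

def detect_threshold(profile: ArrheniusProfile,
                     cfg: DetectionConfig | None = None) -> ThresholdResult:
    """Detect the heat-activation threshold on an Arrhenius profile.

    The steepest component is the contiguous ``min_points``-sample window
    maximizing |slope| among windows with r2 >= ``r2_min`` (ties broken
    toward the window nearest the baseline, i.e. lower temperature, so that
    on an exact two-segment profile the window abuts the breakpoint). The
    baseline is a least-squares line over the colder samples, leaving
    ``guard_gap`` samples between it and the steep window. The threshold is
    the temperature at which the two lines intersect in 1/T coordinates.
    Deterministic given (profile, cfg).
    """
    cfg = cfg or DetectionConfig()
    flags: list[str] = []

    # cap the analysed range at t_max (profile is ascending in 1/T, i.e.
    # descending in temperature, so the cap trims the front of the arrays)
    x_all, y_all = profile.inv_temp_K, profile.log_current
    keep = x_all >= 1.0 / celsius_to_kelvin(cfg.t_max_C)
    x, y = x_all[keep], y_all[keep]
    offset = len(x_all) - len(x)  # samples hotter than t_max sit at the front
    n = len(x)
    if n < 2 * cfg.min_points:
        raise InsufficientDataError(
            f"{n} usable samples below t_max; need {2 * cfg.min_points}"
        )

    w = cfg.min_points
    slopes, r2s = _window_stats(x, y, w)
    ok = r2s >= cfg.r2_min
    if not ok.any():
        raise NoSteepComponentError(
            f"no {w}-sample window reaches r2 >= {cfg.r2_min}"
        )
    # maximal |slope|; ties (to 1e-9 relative, so exactly-collinear windows
    # on a noiseless profile count as tied) break toward the larger start
    # index = larger 1/T = colder window, which abuts the breakpoint
    cand = np.where(ok, np.abs(slopes), -np.inf)
    best = int(np.flatnonzero(cand >= cand.max() * (1.0 - 1e-9))[-1])
    steep = SegmentFit(slope=float(slopes[best]),
                       intercept=float(y[best:best + w].mean()
                                       - slopes[best] * x[best:best + w].mean()),
                       index_range=(offset + best, offset + best + w),
                       r2=float(r2s[best]))

    base_start = best + w + cfg.guard_gap
    if n - base_start < cfg.baseline_min_points:
        raise InsufficientDataError(
            f"only {n - base_start} baseline samples colder than the steep "
            f"window (need {cfg.baseline_min_points})"
        )
    b_slope, b_int, b_r2 = _fit_line(x[base_start:], y[base_start:])
    baseline = SegmentFit(slope=b_slope, intercept=b_int,
                          index_range=(offset + base_start, offset + n),
                          r2=b_r2)

    d_slope = steep.slope - baseline.slope
    if abs(d_slope) < cfg.parallel_tol * max(1.0, abs(steep.slope)):
        raise NoIntersectionError("baseline and steep fits are parallel")
    x_star = (baseline.intercept - steep.intercept) / d_slope
    if x_star <= 0:
        raise NoIntersectionError("intersection at non-physical temperature")
    threshold_C = kelvin_to_celsius(1.0 / x_star)

    t_lo, t_hi = kelvin_to_celsius(1.0 / x[-1]), kelvin_to_celsius(1.0 / x[0])
    if not (t_lo <= threshold_C <= t_hi):
        flags.append("threshold_out_of_range")
    if profile.n_dropped:
        flags.append(f"dropped_nonpositive_samples={profile.n_dropped}")
    return ThresholdResult(threshold_C=float(threshold_C), baseline=baseline,
                           steep=steep, flags=flags)


def compute_q10(steep: SegmentFit, t_ref_C: float) -> float:
    """Q10 from the steep-segment Arrhenius slope.

    Ea = -slope * R (slope in 1/T coordinates); then
    Q10 = exp(Ea * 10 / (R * T_ref * (T_ref + 10))) with T_ref in Kelvin.
    A non-negative slope yields Q10 <= 1 (no heat activation) — callers flag
    it rather than erroring.
    """
    t_ref = celsius_to_kelvin(t_ref_C)
    return float(np.exp(-steep.slope * 10.0 / (t_ref * (t_ref + 10.0))))


def q10_from_ratio(trace: TemperatureTrace, t_ref_C: float) -> float:
    """Empirical Q10 |I|(T_ref + 10) / |I|(T_ref) by linear interpolation."""
    mag = np.abs(trace.current_nA)
    order = np.argsort(trace.temp_C, kind="stable")
    t, m = trace.temp_C[order], mag[order]
    for probe in (t_ref_C, t_ref_C + 10.0):
        if not (t[0] <= probe <= t[-1]):
            raise ExtrapolationError(f"{probe} degC outside the trace range")
    lo = float(np.interp(t_ref_C, t, m))
    hi = float(np.interp(t_ref_C + 10.0, t, m))
    if lo <= 0:
        raise DomainError("non-positive current at the reference temperature")
    return hi / lo


def half_max_activation_temp(trace: TemperatureTrace,
                             baseline: SegmentFit | None,
                             t_max_C: float | None = None) -> float:
    """Lowest temperature at which the heat-gated current reaches half max.

    The gated component is |I|(T) minus the baseline (leak) fit extrapolated
    out of the Arrhenius domain, gated(T) = |I|(T) - exp(baseline(1/T_K));
    pass ``baseline=None`` for the no-subtraction mode. The 50% crossing is
    located by linear interpolation between the bracketing samples.
    """
    order = np.argsort(trace.temp_C, kind="stable")
    t = trace.temp_C[order]
    mag = np.abs(trace.current_nA)[order]
    if t_max_C is not None:
        keep = t <= t_max_C
        t, mag = t[keep], mag[keep]
    if baseline is not None:
        leak = np.exp(baseline.predict(1.0 / celsius_to_kelvin(t)))
        gated = mag - leak
    else:
        gated = mag
    gmax = gated.max()
    if gmax <= 0:
        raise NoActivationError("leak-subtracted current never exceeds zero")
    target = 0.5 * gmax
    above = np.nonzero(gated >= target)[0]
    i = int(above[0])
    if i == 0:
        return float(t[0])
    f = (target - gated[i - 1]) / (gated[i] - gated[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def current_at_temperature(trace: TemperatureTrace, probe_C: float) -> float:
    """Capsaicin-standardized current magnitude at a probe temperature.

    |I|(probe, linearly interpolated) divided by the trace's capsaicin
    reference current magnitude.
    """
    if trace.i_capsaicin_nA is None or not trace.i_capsaicin_nA > 0:
        raise MissingReferenceError("capsaicin reference current missing or <= 0")
    order = np.argsort(trace.temp_C, kind="stable")
    t = trace.temp_C[order]
    if not (t[0] <= probe_C <= t[-1]):
        raise ExtrapolationError(
            f"probe {probe_C} degC outside trace range [{t[0]:.2f}, {t[-1]:.2f}]"
        )
    mag = np.abs(trace.current_nA)[order]
    return float(np.interp(probe_C, t, mag)) / trace.i_capsaicin_nA


# ---------------------------------------------------------------------------
# per-trace orchestration
# ---------------------------------------------------------------------------

def analyze_trace(trace: TemperatureTrace,
                  cfg: DetectionConfig | None = None) -> ThresholdResult:
    """Full per-trace analysis: threshold, Q10, half-max, probe current."""
    cfg = cfg or DetectionConfig()
    profile = to_arrhenius(trace, min_points=2 * cfg.min_points)
    res = detect_threshold(profile, cfg)

    if cfg.q10_t_ref_C is not None:
        t_ref = cfg.q10_t_ref_C
    else:
        s, e = res.steep.index_range
        x = profile.inv_temp_K
        t_ref = kelvin_to_celsius(2.0 / (x[s] + x[e - 1]))
    res.q10 = compute_q10(res.steep, t_ref)
    if res.q10 <= 1.0:
        res.flags.append("q10_nonactivating")

    try:
        res.t_half_act_C = half_max_activation_temp(
            trace, res.baseline if cfg.subtract_leak else None, cfg.t_max_C)
    except NoActivationError:
        res.flags.append("no_activation_for_half_max")

    if trace.i_capsaicin_nA is not None:
        try:
            res.i_at_probe_norm = current_at_temperature(trace, cfg.probe_C)
        except ExtrapolationError:
            res.flags.append("probe_outside_trace_range")
    else:
        res.flags.append("no_capsaicin_reference")
    return res
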