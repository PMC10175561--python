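"""Thermal-shift (DSF) melt-curve normalization and Tm extraction.

Raw dye fluorescence F(T) is normalized against the 20 degC reference and
the global maximum,

    dF(t)/dF_max = (F(t) - F(20 degC)) / (F_max - F(20 degC)),

so the reference sample maps to exactly 0 and the maximum to exactly 1; the
formula is invariant under affine transforms of the raw signal (gain and
offset of the plate reader drop out). The melting temperature Tm is the
midpoint of the unfolding transition, estimated by default from a Boltzmann
sigmoid fitted to the ascending region between the reference and the
fluorescence maximum — truncating at the maximum makes the estimate robust
to the post-peak aggregation decay typical of SYPRO assays. Half-max
interpolation and derivative-maximum estimators are available as
alternatives and as a fallback when the fit does not converge.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lmfit import Model

from .exceptions import (FlatCurveError, InsufficientDataError,
                         MissingReferenceError)
from .synthetic import MeltCurve

__all__ = ["NormalizedMeltCurve", "TmResult", "normalize_melt", "estimate_tm"]

REFERENCE_C = 20.0
REFERENCE_TOL_C = 0.25


@dataclass(frozen=True)
class NormalizedMeltCurve:
    """dF(t)/dF_max curve plus the indices the Tm fit will use."""

    sample_id: str
    temp_C: np.ndarray
    delta_f_norm: np.ndarray
    f_ref_20C: float
    f_max: float
    ref_index: int
    truncation_index: int    # index of the global maximum (inclusive fit end)


@dataclass
class TmResult:
    tm_C: float
    method: str
    params: dict[str, float] = field(default_factory=dict)
    se: dict[str, Optional[float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def normalize_melt(curve: MeltCurve) -> NormalizedMeltCurve:
    """Apply the dF(t)/dF_max normalization to a raw melt curve.

    The 20 degC reference is the nearest grid sample within 0.25 degC; the
    denominator uses the global maximum of the raw curve.
    """
    t, f = curve.temp_C, curve.fluorescence
    ref_index = int(np.argmin(np.abs(t - REFERENCE_C)))
    if abs(t[ref_index] - REFERENCE_C) > REFERENCE_TOL_C:
        raise MissingReferenceError(
            f"no sample within {REFERENCE_TOL_C} degC of the 20 degC reference"
        )
    f_ref = float(f[ref_index])
    max_index = int(np.argmax(f))
    f_max = float(f[max_index])
    if f_max <= f_ref:
        raise FlatCurveError("F_max does not exceed F(20 degC); flat curve")
    norm = (f - f_ref) / (f_max - f_ref)
    return NormalizedMeltCurve(sample_id=curve.sample_id, temp_C=t,
                               delta_f_norm=norm, f_ref_20C=f_ref, f_max=f_max,
                               ref_index=ref_index, truncation_index=max_index)


def _boltzmann(t, tm, k, lower, upper):
    # free plateau levels: the normalized curve is pinned to single (noisy)
    # samples at 0 and 1, so a fixed-amplitude sigmoid would inherit their
    # noise as a midpoint bias
    return lower + (upper - lower) / (1.0 + np.exp((tm - t) / k))


def _half_max_interp(t: np.ndarray, y: np.ndarray) -> float:
    above = np.nonzero(y >= 0.5)[0]
    if above.size == 0:
        raise InsufficientDataError("normalized curve never reaches 0.5")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    f = (0.5 - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def estimate_tm(norm: NormalizedMeltCurve,
                method: str = "boltzmann_fit") -> TmResult:
    """Estimate the melting temperature from a normalized melt curve.

    ``boltzmann_fit`` (default) fits a Boltzmann sigmoid
    lower + (upper - lower)/(1 + exp((tm - T)/k)) with free plateau levels
    to the ascending region from the 20 degC reference to the fluorescence
    maximum and returns the fitted midpoint; ``half_max_interp`` returns the linear
    interpolation of the first 0.5-crossing; ``derivative_max`` the location
    of the steepest rise (with 3-point parabolic refinement). Fit failures
    fall back to half-max interpolation with a flag.
    """
    lo, hi = norm.ref_index, norm.truncation_index
    t = norm.temp_C[lo:hi + 1]
    y = norm.delta_f_norm[lo:hi + 1]
    if len(t) < 8:
        raise InsufficientDataError(
            f"ascending region has {len(t)} samples; need at least 8"
        )

    if method == "half_max_interp":
        return TmResult(tm_C=_half_max_interp(t, y), method=method)

    if method == "derivative_max":
        dy = np.gradient(y, t)
        i = int(np.argmax(dy))
        tm = t[i]
        if 0 < i < len(t) - 1:
            denom = dy[i - 1] - 2 * dy[i] + dy[i + 1]
            if denom < 0:
                tm = tm - 0.5 * (t[i + 1] - t[i]) * (dy[i + 1] - dy[i - 1]) / denom
        return TmResult(tm_C=float(tm), method=method)

    if method != "boltzmann_fit":
        raise ValueError(f"unknown Tm method {method!r}")

    model = Model(_boltzmann, independent_vars=["t"])
    params = model.make_params()
    try:
        tm0 = _half_max_interp(t, y)
    except InsufficientDataError:
        tm0 = float(t[len(t) // 2])
    params["tm"].set(value=tm0, min=float(t[0]), max=float(t[-1]))
    params["k"].set(value=1.0, min=1e-6, max=float(t[-1] - t[0]))
    params["lower"].set(value=float(np.median(y[: max(3, len(y) // 10)])),
                        min=-0.5, max=0.5)
    params["upper"].set(value=float(np.median(y[-max(3, len(y) // 10):])),
                        min=0.5, max=1.5)
    try:
        out = model.fit(y, params, t=t)
        ok = out.success
    except Exception:
        ok = False
    if not ok:
        res = TmResult(tm_C=_half_max_interp(t, y), method="half_max_interp")
        res.flags.append("boltzmann_fit_failed")
        return res
    se = {name: (float(p.stderr) if p.stderr is not None else None)
          for name, p in out.params.items()}
    return TmResult(tm_C=float(out.params["tm"].value), method=method,
                    params={name: float(p.value)
                            for name, p in out.params.items()
                            if name != "tm"},
                    se=se)
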