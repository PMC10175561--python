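"""Synthetic-data generator with known ground truth.

Every pipeline input can be generated here so each analysis stage is
verifiable by parameter recovery:

* heat-ramp current traces from a two-state van't Hoff gating model plus a
  weakly temperature-dependent leak,
* sigmoidal (Hill) agonist and proton dose-response tables,
* two-state protein-unfolding melt curves,
* mutant panels in which the activation threshold varies linearly with the
  mutational stability change ddG.

The gating model: a channel with a single closed-open equilibrium whose
open probability follows

    P(T) = 1 / (1 + exp((dH - T*dS) / (R*T)))

with activation enthalpy ``dH`` (kJ/mol) and entropy ``dS`` (kJ/(mol K)).
P = 1/2 at the half-activation temperature T_half = dH/dS; a large positive
dH makes the channel steeply heat-activated, which is what produces the
baseline-then-steep shape of the Arrhenius profile that threshold detection
assumes. Inward current at -80 mV is stored with negative sign; analyses
operate on magnitudes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import KELVIN_OFFSET, R_GAS_KJ, RampProtocolConfig, celsius_to_kelvin
from .exceptions import DomainError

__all__ = [
    "GatingModelParams",
    "RampProtocol",
    "TemperatureTrace",
    "MeltCurve",
    "open_probability",
    "simulate_heat_ramp",
    "simulate_dose_response",
    "simulate_melt_curve",
    "simulate_mutant_panel",
]

# RampProtocol is the same record the pipeline config uses.
RampProtocol = RampProtocolConfig


@dataclass(frozen=True)
class GatingModelParams:
    """Parameters of the synthetic two-state channel.

    dH : activation enthalpy, kJ/mol (> 0)
    dS : activation entropy, kJ/(mol K) (> 0); T_half = dH/dS
    i_max : maximal gated current magnitude at the holding potential, nA
    leak_ref : leak current magnitude at 25 degC, nA
    q10_leak : leak temperature coefficient (fold change per 10 degC)
    noise_sd : multiplicative Gaussian noise SD (dimensionless fraction)
    seed : random seed for the noise stream
    """

    dH: float
    dS: float
    i_max: float = 4000.0
    leak_ref: float = 150.0
    q10_leak: float = 1.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dH <= 0 or self.dS <= 0:
            raise DomainError("dH and dS must be positive")
        if not (KELVIN_OFFSET <= self.t_half_K <= KELVIN_OFFSET + 100.0):
            raise DomainError(
                f"T_half = dH/dS = {self.t_half_K:.2f} K outside [273.15, 373.15] K"
            )
        if self.i_max <= 0:
            raise DomainError("i_max must be positive")
        if self.leak_ref < 0:
            raise DomainError("leak_ref must be non-negative")
        if self.q10_leak < 1:
            raise DomainError("q10_leak must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")

    @property
    def t_half_K(self) -> float:
        return self.dH / self.dS

    @property
    def t_half_C(self) -> float:
        return self.t_half_K - KELVIN_OFFSET

    @classmethod
    def from_t_half(cls, t_half_C: float, dH: float = 250.0, **kw) -> "GatingModelParams":
        """Build params from a target half-activation temperature in degC."""
        return cls(dH=dH, dS=dH / celsius_to_kelvin(t_half_C), **kw)


@dataclass(frozen=True)
class TemperatureTrace:
    """A single heat-ramp recording at the holding potential.

    ``current_nA`` carries inward currents as negative values; analyses use
    magnitudes. ``i_capsaicin_nA`` is the same cell's saturating capsaicin
    response magnitude, used for standardization.
    """

    trace_id: str
    time_s: np.ndarray
    temp_C: np.ndarray
    current_nA: np.ndarray
    i_capsaicin_nA: Optional[float] = None

    def __post_init__(self):
        t, temp, cur = (np.asarray(a, dtype=float)
                        for a in (self.time_s, self.temp_C, self.current_nA))
        if not (len(t) == len(temp) == len(cur)):
            raise DomainError("time/temp/current arrays must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("time must be strictly increasing")
        if not np.all(np.isfinite(temp)) or temp.min() < 0 or temp.max() > 100:
            raise DomainError("temp_C must be finite and within [0, 100]")
        if self.i_capsaicin_nA is not None and not self.i_capsaicin_nA > 0:
            raise DomainError("i_capsaicin_nA must be positive when present")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "temp_C", temp)
        object.__setattr__(self, "current_nA", cur)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class MeltCurve:
    """Raw thermal-shift fluorescence vs temperature for one sample."""

    sample_id: str
    temp_C: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temp_C, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if len(t) != len(f):
            raise DomainError("temp and fluorescence must have equal length")
        if not np.all(np.diff(t) > 0):
            raise DomainError("temperature grid must be strictly increasing")
        if not (t.min() <= 20.0 <= t.max()):
            raise DomainError("grid must cover the 20 degC normalization reference")
        if not np.all(np.isfinite(f)) or f.min() < 0:
            raise DomainError("fluorescence must be finite and non-negative")
        object.__setattr__(self, "temp_C", t)
        object.__setattr__(self, "fluorescence", f)


# ---------------------------------------------------------------------------
# gating model
# ---------------------------------------------------------------------------

def open_probability(temp_K, params: GatingModelParams):
    """Two-state van't Hoff open probability at absolute temperature.

    P(T) = 1 / (1 + exp((dH - T*dS) / (R*T))); strictly increasing in T for
    dH > 0, with P(dH/dS) = 1/2. Accepts scalars or arrays.
    """
    t = np.asarray(temp_K, dtype=float)
    if np.any(t <= 0):
        raise DomainError("absolute temperature must be positive")
    x = (params.dH - t * params.dS) / (R_GAS_KJ * t)
    p = 1.0 / (1.0 + np.exp(x))
    return p if p.ndim else float(p)


def _leak_magnitude(temp_C, params: GatingModelParams):
    return params.leak_ref * params.q10_leak ** ((np.asarray(temp_C) - 25.0) / 10.0)


def simulate_heat_ramp(params: GatingModelParams,
                       protocol: RampProtocol | None = None,
                       trace_id: str = "sim",
                       i_capsaicin_nA: Optional[float] = None) -> TemperatureTrace:
    """Simulate one heat-ramp recording at -80 mV.

    Current magnitude per sample is
    ``[leak_ref * q10_leak**((T-25)/10) + i_max * P(T)] * (1 + eps)`` with
    ``eps ~ N(0, noise_sd^2)`` drawn from a generator seeded by
    ``params.seed`` — the same seed reproduces the trace bit-for-bit. The
    inward sign convention (negative) is applied last.

    The capsaicin reference defaults to ``i_max``: a saturating agonist dose
    opens essentially every channel, so the maximal capsaicin response equals
    the maximal gated current of the model cell.
    """
    protocol = protocol or RampProtocol()
    duration = (protocol.t_stop_C - protocol.t_start_C) / protocol.rate_C_per_s
    n = int(np.floor(duration * protocol.sample_hz)) + 1
    time_s = np.arange(n) / protocol.sample_hz
    temp_C = protocol.t_start_C + protocol.rate_C_per_s * time_s
    temp_C = np.minimum(temp_C, protocol.t_stop_C)

    gated = params.i_max * open_probability(celsius_to_kelvin(temp_C), params)
    magnitude = _leak_magnitude(temp_C, params) + gated
    rng = np.random.default_rng(params.seed)
    eps = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
    magnitude = magnitude * (1.0 + eps)

    if i_capsaicin_nA is None:
        i_capsaicin_nA = params.i_max
    return TemperatureTrace(trace_id=trace_id, time_s=time_s, temp_C=temp_C,
                            current_nA=-magnitude, i_capsaicin_nA=i_capsaicin_nA)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def hill_response(conc, ec50: float, hill_n: float, r_max: float):
    """Hill curve r(C) = r_max * C^n / (ec50^n + C^n); r(0) = 0."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(c > 0, c, np.nan) ** hill_n
        r = r_max * cn / (ec50 ** hill_n + cn)
    r = np.where(c > 0, r, 0.0)
    return r if r.ndim else float(r)


def simulate_dose_response(ec50: float, hill_n: float, r_max: float,
                           doses: Sequence[float], noise_sd: float = 0.0,
                           seed: int = 0, *, construct: str = "sim",
                           stimulus_kind: str = "capsaicin",
                           n_replicates: int = 1) -> pd.DataFrame:
    """Simulate a tidy dose-response table.

    For ``stimulus_kind='capsaicin'`` doses are concentrations in uM and
    ``ec50`` is in uM. For ``'acid'`` doses are pH units; the response is
    computed on the molar proton concentration C = 10**(-pH) and ``ec50``
    must then be given in molar [H+]. Noise is multiplicative Gaussian.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise DomainError("dose list must be non-empty")
    if ec50 <= 0 or hill_n <= 0:
        raise DomainError("ec50 and hill_n must be positive")
    if stimulus_kind not in ("capsaicin", "acid"):
        raise DomainError(f"unknown stimulus_kind {stimulus_kind!r}")
    if stimulus_kind == "capsaicin" and np.any(doses <= 0):
        raise DomainError("capsaicin doses must be positive")
    if stimulus_kind == "acid" and (np.any(doses <= 0) or np.any(doses >= 14)):
        raise DomainError("pH doses must lie in (0, 14)")

    conc = 10.0 ** (-doses) if stimulus_kind == "acid" else doses
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mean = hill_response(conc, ec50, hill_n, r_max)
        eps = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
        for d, r in zip(doses, mean * (1.0 + eps)):
            rows.append((construct, stimulus_kind, d, rep, r))
    return pd.DataFrame(rows, columns=["construct", "stimulus_kind", "dose",
                                       "replicate", "response"])


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def default_melt_grid() -> np.ndarray:
    """Temperature grid 10-95 degC sampled every 0.5 degC."""
    return np.arange(10.0, 95.0 + 1e-9, 0.5)


def simulate_melt_curve(tm_C: float, dH_unfold: float = 300.0,
                        f_native: float = 1000.0, f_unfolded: float = 5000.0,
                        grid: Optional[np.ndarray] = None,
                        noise_sd: float = 0.0, seed: int = 0, *,
                        sample_id: str = "sim",
                        post_peak_decay_per_C: float = 0.0,
                        decay_onset_C: Optional[float] = None) -> MeltCurve:
    """Simulate a two-state unfolding melt curve.

    F(T) = f_native + (f_unfolded - f_native) * u(T) + eps, where
    u(T) = 1 / (1 + exp(dH_unfold/R * (1/T_K - 1/Tm_K))) is the van't Hoff
    unfolded fraction (u(Tm) = 1/2, ``dH_unfold`` in kJ/mol). ``noise_sd``
    is an additive Gaussian SD expressed as a fraction of the fluorescence
    amplitude (f_unfolded - f_native).

    Dye-aggregation decay after the fluorescence maximum (typical of SYPRO
    assays) is off by default; set ``post_peak_decay_per_C`` > 0 to ramp the
    signal down linearly above ``decay_onset_C`` (default Tm + 10) so that
    truncation-at-maximum rules can be exercised.
    """
    t = default_melt_grid() if grid is None else np.asarray(grid, dtype=float)
    if not (t.min() <= 20.0 <= t.max()):
        raise DomainError("grid must cover the 20 degC normalization reference")
    if not (t.min() < tm_C < t.max()):
        raise DomainError("tm_C must lie inside the temperature grid")
    if not f_unfolded > f_native:
        raise DomainError("f_unfolded must exceed f_native")

    t_k = celsius_to_kelvin(t)
    tm_k = celsius_to_kelvin(tm_C)
    u = 1.0 / (1.0 + np.exp(dH_unfold / R_GAS_KJ * (1.0 / t_k - 1.0 / tm_k)))
    amp = f_unfolded - f_native
    f = f_native + amp * u
    if post_peak_decay_per_C > 0:
        onset = tm_C + 10.0 if decay_onset_C is None else decay_onset_C
        f = f - amp * post_peak_decay_per_C * np.maximum(t - onset, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd * amp, size=t.size)
    return MeltCurve(sample_id=sample_id, temp_C=t,
                     fluorescence=np.maximum(f, 0.0))


# ---------------------------------------------------------------------------
# mutant panels
# ---------------------------------------------------------------------------

def simulate_mutant_panel(n_mutants: int, t0_C: float,
                          slope_C_per_kcal: float,
                          ddg_range: tuple[float, float],
                          noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate a ddG / activation-threshold mutant panel.

    ddG values (kcal/mol) are drawn uniformly over ``ddg_range``; thresholds
    follow ``t0_C + slope_C_per_kcal * ddG + eps`` with additive Gaussian
    noise in degC. A negative slope emulates destabilizing mutations lowering
    the heat-activation threshold (inverse stability/threshold relation).

    Returns a tidy frame (mutant_id, position, ddG_kcal_mol, threshold_C);
    a zero-width ``ddg_range`` with several mutants sets
    ``df.attrs['warnings']`` because the downstream correlation is undefined.
    """
    if n_mutants < 3:
        raise DomainError("need at least 3 mutants for a correlation panel")
    lo, hi = ddg_range
    if hi < lo:
        raise DomainError("ddg_range must be (low, high)")
    rng = np.random.default_rng(seed)
    ddg = rng.uniform(lo, hi, size=n_mutants)
    eps = rng.normal(0.0, noise_sd, size=n_mutants) if noise_sd > 0 else 0.0
    thr = t0_C + slope_C_per_kcal * ddg + eps
    df = pd.DataFrame({
        "mutant_id": [f"M{i + 1:02d}" for i in range(n_mutants)],
        "position": [f"P{i + 1:02d}" for i in range(n_mutants)],
        "ddG_kcal_mol": ddg,
        "threshold_C": thr,
    })
    df.attrs["warnings"] = (
        ["degenerate ddg_range: correlation undefined downstream"]
        if hi == lo and n_mutants > 1 else []
    )
    return df
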