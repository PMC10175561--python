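"""Sigmoidal concentration-response fitting.

Capsaicin responses (concentration in uM, recorded at -80 mV) and proton
responses (pH, recorded at +80 mV) are fitted with the Hill equation

    r(C) = r_max * C^n / (ec50^n + C^n)

by bounded least squares with multi-start initialization. Acid tables are
converted from pH to molar proton concentration C = 10**(-pH) before
fitting, and the potency is additionally reported as pH50 = -log10(ec50).
Fitting is scale-free: rescaling all responses rescales r_max and leaves
ec50 and the Hill coefficient n unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lmfit import Model

from .exceptions import DegenerateDataError, DomainError, FitFailureError
from .synthetic import hill_response

__all__ = ["HillFit", "fit_hill"]


@dataclass
class HillFit:
    """Result of a Hill fit.

    For acid data ``ec50`` is molar [H+] and ``ph50`` its -log10; for
    capsaicin ``ec50`` is in uM and ``ph50`` is None.
    """

    ec50: float
    hill_n: float
    r_max: float
    rss: float
    se: dict[str, Optional[float]]
    converged: bool
    stimulus_kind: str = "capsaicin"
    ph50: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def _prepare(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    required = {"dose", "response"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"dose table missing columns {sorted(missing)}")
    kind = "capsaicin"
    if "stimulus_kind" in table.columns:
        kinds = set(table["stimulus_kind"].unique())
        if len(kinds) != 1:
            raise DomainError("fit one stimulus kind at a time")
        kind = kinds.pop()
    dose = table["dose"].to_numpy(dtype=float)
    resp = table["response"].to_numpy(dtype=float)
    if np.any(resp < 0):
        raise DomainError("responses must be non-negative")
    conc = 10.0 ** (-dose) if kind == "acid" else dose
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    return conc, resp, kind


def fit_hill(table: pd.DataFrame, *, n_bounds: tuple[float, float] = (0.3, 10.0),
             n_starts: int = 5) -> HillFit:
    """Fit the Hill equation to a tidy dose-response table.

    ``table`` needs columns ``dose`` and ``response`` (``stimulus_kind``
    optional; 'acid' doses are pH units). At least 3 distinct doses are
    required. ec50 is initialized at the geometric median dose with n = 1
    and r_max at the maximal response; ``n_starts`` starts jitter log-ec50
    over two decades and the lowest-RSS converged fit wins.
    """
    conc, resp, kind = _prepare(table)
    if len(np.unique(conc)) < 3:
        raise DomainError("need at least 3 distinct doses")
    if np.ptp(resp) == 0:
        raise DegenerateDataError("all responses equal; Hill fit is undefined")

    log_c = np.log(conc)
    ec50_0 = float(np.exp(np.median(log_c)))
    r_max_0 = float(resp.max())
    model = Model(hill_response, independent_vars=["conc"])
    jitters = np.linspace(-1.0, 1.0, n_starts)  # decades around the median dose

    best = None
    for j in jitters:
        params = model.make_params()
        params["ec50"].set(value=ec50_0 * 10.0 ** j, min=conc.min() * 1e-4,
                           max=conc.max() * 1e4)
        params["hill_n"].set(value=1.0, min=n_bounds[0], max=n_bounds[1])
        params["r_max"].set(value=r_max_0 if r_max_0 > 0 else 1.0, min=1e-12)
        try:
            out = model.fit(resp, params, conc=conc)
        except Exception:
            continue
        if not out.success:
            continue
        rss = float(np.sum(out.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, out)
    if best is None:
        raise FitFailureError(
            f"Hill fit did not converge in any of {n_starts} starts"
        )
    rss, out = best
    se = {name: (float(p.stderr) if p.stderr is not None else None)
          for name, p in out.params.items()}
    ec50 = float(out.params["ec50"].value)
    return HillFit(
        ec50=ec50,
        hill_n=float(out.params["hill_n"].value),
        r_max=float(out.params["r_max"].value),
        rss=rss,
        se=se,
        converged=True,
        stimulus_kind=kind,
        ph50=(-float(np.log10(ec50)) if kind == "acid" else None),
    )
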