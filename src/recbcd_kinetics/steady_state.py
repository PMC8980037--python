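"""Steady-state ATPase activity: the quadratic (tight-binding) rate law.

Because the assay can be run with enzyme concentrations that are not
negligible against K_m, the velocity is fitted with the quadratic form of
the Briggs–Haldane equation (free-substrate depletion handled exactly)
rather than the plain Michaelis–Menten hyperbola.  With E_T ≪ K_m the two
coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DataError, FitError

__all__ = ["AtpaseCurve", "AtpaseFitResult", "briggs_haldane", "fit_atpase"]


@dataclass
class AtpaseCurve:
    atp: np.ndarray  # total [ATP], µM
    rate: np.ndarray  # turnover velocity, s⁻¹
    enzyme: float  # total enzyme, µM
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.atp = np.asarray(self.atp, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.diff(self.atp) <= 0):
            raise DataError("ATP concentrations must be increasing")
        if self.enzyme <= 0:
            raise DataError("enzyme concentration must be > 0")


@dataclass
class AtpaseFitResult:
    k0: float  # basal rate, s⁻¹
    kcat: float  # saturating turnover, s⁻¹
    Km: float  # apparent Michaelis constant, µM
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan


def briggs_haldane(atp_total, enzyme_total, k0, kcat, Km):
    """Quadratic Briggs–Haldane velocity; v(0) = k0, v(∞) = kcat."""
    S = np.asarray(atp_total, dtype=float)
    E = enzyme_total
    b = Km + E + S
    disc = np.clip(b * b - 4.0 * E * S, 0.0, None)  # rounding guard
    frac = (b - np.sqrt(disc)) / (2.0 * E)
    out = k0 + (kcat - k0) * frac
    return out if out.ndim else float(out)


def fit_atpase(curve: AtpaseCurve) -> AtpaseFitResult:
    """Least-squares fit of (k0, kcat, Km) with the enzyme total held fixed.

    E_T is a known assay quantity; co-estimating it at E_T ≪ K_m is
    unidentifiable, so it is never varied.
    """
    if len(curve.atp) < 5:
        raise FitError("need at least 5 points spanning below and above Km")
    if np.all(curve.rate == 0):
        warnings.warn("all-zero velocities: Km is unidentifiable", stacklevel=2)
        return AtpaseFitResult(k0=0.0, kcat=0.0, Km=np.nan)

    weights = np.ones_like(curve.rate)
    known_variance = curve.sem is not None and bool(np.all(curve.sem > 0))
    if known_variance:
        weights = 1.0 / curve.sem

    params = lmfit.Parameters()
    params.add("k0", value=float(max(curve.rate[0], 0.0)), min=0.0)
    params.add("kcat", value=float(curve.rate.max()), min=0.0)
    params.add("Km", value=float(np.median(curve.atp)), min=1e-9)

    def resid(p):
        y = briggs_haldane(curve.atp, curve.enzyme, p["k0"].value, p["kcat"].value, p["Km"].value)
        return (y - curve.rate) * weights

    result = lmfit.minimize(resid, params, method="leastsq", scale_covar=not known_variance)
    if not result.success:
        raise FitError("Briggs-Haldane fit did not converge")
    stderr = {k: (v.stderr if v.stderr is not None else np.nan) for k, v in result.params.items()}
    r = resid(result.params)
    return AtpaseFitResult(
        k0=result.params["k0"].value,
        kcat=result.params["kcat"].value,
        Km=result.params["Km"].value,
        stderr=stderr,
        rss=float(np.sum(r**2)),
    )
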