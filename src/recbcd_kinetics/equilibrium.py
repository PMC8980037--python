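"""Equilibrium binding analysis: biphasic isotherms and dialysis stoichiometry.

Titration isotherms of fluorescent nucleotide analogs binding RecBCD are
biphasic: a strong, weakly cooperative phase (the catalytic sites) plus a
weak, cooperative phase (the auxiliary sites).  Phenomenologically the
curves are described by the sum of two Hill terms,

    y = p / (1 + (Ks/[mN])^ns) + (1 - p) / (1 + (Kw/[mN])^nw),

with partition coefficient p ∈ [0, 1].  The Hill coefficients are reported
as fitted but are never converted into site counts — that relation only
holds at infinite cooperativity.

Equilibrium dialysis gives a model-free bound count per enzyme through
mass conservation, [N]_i = 2[N]_f + n·[protein].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DataError, FitError, InvalidArgumentError
from .model_core import ExperimentalCondition, ModelParameters, resolve_rates, site_occupancies

__all__ = [
    "BindingIsotherm",
    "HillFitResult",
    "DialysisMeasurement",
    "double_hill",
    "fit_double_hill",
    "fit_single_hill",
    "model_isotherm",
    "dialysis_bound_count",
]

MIN_ISOTHERM_POINTS = 6


@dataclass
class BindingIsotherm:
    """A titration curve: normalized signal vs ligand concentration (µM)."""

    conc: np.ndarray
    signal: np.ndarray
    sem: np.ndarray | None = None
    condition: ExperimentalCondition = field(default_factory=ExperimentalCondition)

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if self.conc.ndim != 1 or self.conc.shape != self.signal.shape:
            raise DataError("conc and signal must be matching 1-D arrays")
        if np.any(np.diff(self.conc) <= 0):
            raise DataError("concentrations must be strictly increasing")


@dataclass
class HillFitResult:
    p: float
    Ks: float
    ns: float
    Kw: float
    nw: float
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan

    def as_dict(self) -> dict:
        return {
            "p": self.p,
            "Ks_uM": self.Ks,
            "ns": self.ns,
            "Kw_uM": self.Kw,
            "nw": self.nw,
            "stderr": self.stderr,
            "rss": self.rss,
        }


@dataclass
class DialysisMeasurement:
    """Initial/final free-ligand concentrations across a dialysis membrane."""

    ligand_initial: float  # [N]_i, µM
    ligand_final: float  # [N]_f, µM (free chamber)
    protein: float  # µM

    def __post_init__(self):
        if self.protein <= 0:
            raise InvalidArgumentError("protein concentration must be > 0")
        if self.ligand_final < 0 or self.ligand_initial < 0:
            raise InvalidArgumentError("concentrations must be >= 0")


def double_hill(mN, p, Ks, ns, Kw, nw):
    """Sum-of-two-Hill-terms isotherm; handles mN = 0 as the limit 0."""
    mN = np.asarray(mN, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        strong = np.where(mN > 0, 1.0 / (1.0 + (Ks / np.where(mN > 0, mN, 1.0)) ** ns), 0.0)
        weak = np.where(mN > 0, 1.0 / (1.0 + (Kw / np.where(mN > 0, mN, 1.0)) ** nw), 0.0)
    out = p * strong + (1.0 - p) * weak
    return out if out.ndim else float(out)


def _hill_residual(params, conc, signal, weights):
    y = double_hill(
        conc,
        params["p"].value,
        params["Ks"].value,
        params["ns"].value,
        params["Kw"].value,
        params["nw"].value,
    )
    return (y - signal) * weights


def _default_init(iso: BindingIsotherm) -> dict:
    # Ks from the concentration nearest half of the first-phase amplitude;
    # the phases overlap, so the fit is multimodal and needs a sane start.
    smax = float(np.max(iso.signal))
    half = 0.25 * smax
    idx = int(np.argmin(np.abs(iso.signal - half)))
    Ks0 = float(max(iso.conc[idx], iso.conc[iso.conc > 0].min() if np.any(iso.conc > 0) else 1.0))
    return {"p": 0.5, "Ks": Ks0, "ns": 1.0, "Kw": 10.0 * Ks0, "nw": 1.0}


def fit_double_hill(
    iso: BindingIsotherm,
    init: HillFitResult | dict | None = None,
    weighted: bool = True,
) -> HillFitResult:
    """Weighted least-squares fit of the biphasic isotherm.

    Weights are 1/sem when per-point uncertainties are provided and
    ``weighted`` is set.  ``p`` is constrained to [0, 1]; a fit pinned at
    that boundary (single-phase data) triggers a warning rather than an
    error.
    """
    if len(iso.conc) < MIN_ISOTHERM_POINTS:
        raise FitError(
            f"need at least {MIN_ISOTHERM_POINTS} points to fit a biphasic isotherm"
        )
    if init is None:
        start = _default_init(iso)
    elif isinstance(init, HillFitResult):
        start = {"p": init.p, "Ks": init.Ks, "ns": init.ns, "Kw": init.Kw, "nw": init.nw}
    else:
        start = dict(init)

    weights = np.ones_like(iso.signal)
    known_variance = weighted and iso.sem is not None and bool(np.all(iso.sem > 0))
    if known_variance:
        # stated measurement errors: the covariance must not be rescaled by
        # the reduced chi-square or the standard errors lose calibration
        weights = 1.0 / iso.sem

    params = lmfit.Parameters()
    params.add("p", value=start["p"], min=0.0, max=1.0)
    params.add("Ks", value=start["Ks"], min=1e-6)
    params.add("ns", value=start["ns"], min=1e-3)
    params.add("Kw", value=start["Kw"], min=1e-6)
    params.add("nw", value=start["nw"], min=1e-3)

    result = lmfit.minimize(
        _hill_residual,
        params,
        args=(iso.conc, iso.signal, weights),
        method="leastsq",
        scale_covar=not known_variance,
    )
    if not result.success:
        best = {k: v.value for k, v in result.params.items()}
        raise FitError("double-Hill fit did not converge", best_so_far=best)
    values = {k: v.value for k, v in result.params.items()}
    # the fit is symmetric in the two phases; report the stronger one as Ks
    if values["Ks"] > values["Kw"]:
        values["Ks"], values["Kw"] = values["Kw"], values["Ks"]
        values["ns"], values["nw"] = values["nw"], values["ns"]
        values["p"] = 1.0 - values["p"]
    if values["p"] > 0.99 or values["p"] < 0.01:
        warnings.warn(
            "partition coefficient pinned at a boundary: data may be single-phase",
            stacklevel=2,
        )
    stderr = {k: (v.stderr if v.stderr is not None else np.nan) for k, v in result.params.items()}
    resid = _hill_residual(result.params, iso.conc, iso.signal, np.ones_like(iso.signal))
    return HillFitResult(
        p=values["p"],
        Ks=values["Ks"],
        ns=values["ns"],
        Kw=values["Kw"],
        nw=values["nw"],
        stderr=stderr,
        rss=float(np.sum(resid**2)),
    )


def fit_single_hill(conc, signal):
    """Best single-Hill fit; returns (K, n, amplitude, r_squared).

    Used to quantify how monophasic a curve is (e.g. with the auxiliary
    sites disabled the model isotherm collapses to one phase).
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    params = lmfit.Parameters()
    pos = conc[conc > 0]
    params.add("K", value=float(np.median(pos)) if pos.size else 1.0, min=1e-6)
    params.add("n", value=1.0, min=1e-3)
    params.add("amp", value=float(signal.max()) if signal.size else 1.0, min=1e-12)

    def resid(p):
        with np.errstate(divide="ignore", over="ignore"):
            y = np.where(
                conc > 0,
                p["amp"].value / (1.0 + (p["K"].value / np.where(conc > 0, conc, 1.0)) ** p["n"].value),
                0.0,
            )
        return y - signal

    result = lmfit.minimize(resid, params, method="leastsq")
    r = resid(result.params)
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    r2 = 1.0 - float(np.sum(r**2)) / ss_tot if ss_tot > 0 else 1.0
    return (
        result.params["K"].value,
        result.params["n"].value,
        result.params["amp"].value,
        r2,
    )


def model_isotherm(
    params: ModelParameters,
    condition: ExperimentalCondition,
    concentrations,
    signal_weights: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Model-predicted titration signal at the given free concentrations.

    The catalytic and auxiliary sites may report with different FRET
    efficiencies, so the signal is w_c·⟨c⟩ + w_w·⟨w⟩, normalized to its
    value at the largest measured concentration (titrations are scaled the
    same way).
    """
    w_cat, w_weak = signal_weights
    if w_cat < 0 or w_weak < 0:
        raise InvalidArgumentError("signal weights must be >= 0")
    if w_cat == 0 and w_weak == 0:
        raise InvalidArgumentError("at least one signal weight must be positive")
    conc = np.asarray(concentrations, dtype=float)
    rates = resolve_rates(params, condition)
    Ks = 0.0 if not np.isfinite(rates.Ks) else rates.Ks
    Kw = 0.0 if not np.isfinite(rates.Kw) else rates.Kw
    mw, mc = site_occupancies(
        Ks, Kw, rates.coop_a, conc, params.n_weak_sites, params.n_cat_sites
    )
    raw = w_cat * mc + w_weak * mw
    top = raw[-1] if raw.ndim else raw
    if top <= 0:
        return np.zeros_like(raw)
    return raw / top


def dialysis_bound_count(m: DialysisMeasurement) -> float:
    """Bound nucleotides per enzyme, n = ([N]_i − 2[N]_f)/[protein].

    The factor of two reflects the equal-volume chambers: at equilibrium the
    free ligand concentration is the same on both sides of the membrane.  A
    negative count (measurement noise) is returned with a warning.
    """
    n = (m.ligand_initial - 2.0 * m.ligand_final) / m.protein
    if n < 0:
        warnings.warn("negative bound count: measurement noise", stacklevel=2)
    return n
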