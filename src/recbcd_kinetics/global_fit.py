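"""Joint estimation of the kinetic scheme from heterogeneous experiments.

The free parameter vector has eleven entries: the catalytic rates ks_on and
ks_off, the reverse transfer rate, the cooperativity factor a, the
per-site catalysis rate vmax, and the six coefficients of the
condition-linear laws for the auxiliary on-rate (vs adenosine), auxiliary
off-rate (vs NaCl) and forward transfer rate (vs NaCl).  The objective is
the sum over experiment blocks (isotherms, dialysis, k_obs curves,
unwinding rates) of the mean squared uncertainty-normalized residual, so
that no modality dominates by sheer record count.

The published global-search strategy is approximated here by seeded
multi-start bounded least squares in log-magnitude space: reproducible,
portable, and adequate for the landscape this model presents.  Robustness
is probed with a bootstrap Monte Carlo (perturb every record by its stated
uncertainty, refit, summarize each parameter's histogram by a Gaussian),
and the auxiliary-site count is selected by refitting the scheme with
different weak-site numbers and comparing a small-sample-corrected
information criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .equilibrium import BindingIsotherm, DialysisMeasurement, model_isotherm, dialysis_bound_count
from .errors import FitError, InvalidArgumentError
from .model_core import (
    ExperimentalCondition,
    ModelParameters,
    biexp_rates,
    mean_occupancy,
    resolve_rates,
    steady_unwinding_rate,
)
from .transients import KobsCurve

__all__ = [
    "Dataset",
    "UnwindingRateRecord",
    "TemperatureModel",
    "GlobalFitResult",
    "BootstrapResult",
    "FREE_PARAMETER_NAMES",
    "objective",
    "residual_vector",
    "run_global_fit",
    "bootstrap",
    "select_weak_site_count",
    "predict_dialysis_count",
]

# The 11 free parameters of the scheme (condition-linear substitutions
# included); every other ModelParameters field is structural.
FREE_PARAMETER_NAMES = (
    "ks_on",
    "ks_off",
    "ktr_rev",
    "coop_a",
    "vmax",
    "kw_on_slope_ado",
    "kw_on_intercept",
    "kw_off_slope_nacl",
    "kw_off_intercept",
    "ktr_fwd_slope_nacl",
    "ktr_fwd_intercept",
)

# Sign convention: condition slopes are "nonnegative linear decreasing",
# i.e. the slope itself is <= 0 and the evaluated rate is clamped at zero.
_NEGATIVE_PARAMS = frozenset(
    {"kw_on_slope_ado", "kw_off_slope_nacl", "ktr_fwd_slope_nacl"}
)

DEFAULT_BOUNDS = {
    "ks_on": (0.05, 500.0),
    "ks_off": (1.0, 2e4),
    "ktr_rev": (0.5, 1e5),
    "coop_a": (1.0, 200.0),
    "vmax": (10.0, 1e5),
    "kw_on_slope_ado": (1e-4, 10.0),  # magnitude; sign is negative
    "kw_on_intercept": (1e-3, 50.0),
    "kw_off_slope_nacl": (1e-3, 100.0),  # magnitude
    "kw_off_intercept": (1.0, 2e4),
    "ktr_fwd_slope_nacl": (1e-2, 1e4),  # magnitude
    "ktr_fwd_intercept": (10.0, 1e7),
}


@dataclass
class UnwindingRateRecord:
    rate: float  # bp·s⁻¹
    stderr: float
    condition: ExperimentalCondition


@dataclass
class Dataset:
    """Heterogeneous experiment collection entering the global fit.

    Isotherm records carry ``signal_weights`` (relative reporter efficiency
    of catalytic vs auxiliary sites), treated as a known assay calibration.
    """

    isotherms: list = field(default_factory=list)  # (BindingIsotherm, weights)
    dialysis: list = field(default_factory=list)  # (DialysisMeasurement, stderr)
    kobs_curves: list[KobsCurve] = field(default_factory=list)
    unwinding: list[UnwindingRateRecord] = field(default_factory=list)

    def conditions(self):
        conds = [iso.condition for iso, _ in self.isotherms]
        conds += [c.condition for c in self.kobs_curves]
        conds += [u.condition for u in self.unwinding]
        return conds

    def n_records(self) -> int:
        n = sum(len(iso.conc) for iso, _ in self.isotherms)
        n += len(self.dialysis)
        n += sum(len(c.conc) for c in self.kobs_curves)
        n += len(self.unwinding)
        return n


@dataclass(frozen=True)
class TemperatureModel:
    """Temperature → rate multiplier.  Identity unless a Q10 is supplied."""

    q10: float | None = None
    reference_c: float = 25.0

    def multiplier(self, temperature_c: float) -> float:
        if self.q10 is None:
            return 1.0
        m = self.q10 ** ((temperature_c - self.reference_c) / 10.0)
        if m <= 0:
            raise InvalidArgumentError("temperature multiplier must be > 0")
        return m


def _scale_params(params: ModelParameters, m: float) -> ModelParameters:
    """Multiply every rate constant (and rate-law coefficient) by m."""
    if m == 1.0:
        return params
    return params.replace(
        ks_on=params.ks_on * m,
        ks_off=params.ks_off * m,
        kw_on_intercept=params.kw_on_intercept * m,
        kw_on_slope_ado=params.kw_on_slope_ado * m,
        kw_off_intercept=params.kw_off_intercept * m,
        kw_off_slope_nacl=params.kw_off_slope_nacl * m,
        ktr_fwd_intercept=params.ktr_fwd_intercept * m,
        ktr_fwd_slope_nacl=params.ktr_fwd_slope_nacl * m,
        ktr_rev=params.ktr_rev * m,
        vmax=params.vmax * m,
    )


def predict_dialysis_count(
    params: ModelParameters,
    condition: ExperimentalCondition,
    protein_uM: float,
    ligand_initial_uM: float,
) -> float:
    """Bound count in a closed two-chamber dialysis at equilibrium.

    Solves 2·[N]_f + n([N]_f)·[protein] = [N]_i for the free concentration,
    where n is the model mean occupancy at the free ligand level.
    """
    rates = resolve_rates(params, condition)
    Ks = rates.Ks if np.isfinite(rates.Ks) else 0.0
    Kw = rates.Kw if np.isfinite(rates.Kw) else 0.0

    def occ(f):
        return float(
            mean_occupancy(Ks, Kw, rates.coop_a, f,
                           n_weak=params.n_weak_sites, n_cat=params.n_cat_sites)
        )

    def g(f):
        return 2.0 * f + protein_uM * occ(f) - ligand_initial_uM

    hi = ligand_initial_uM / 2.0
    if g(hi) <= 0:
        return occ(hi)
    f_root = brentq(g, 1e-12, hi, xtol=1e-10, rtol=1e-12)
    return occ(f_root)


def _experiment_residuals(params, dataset: Dataset, temp_model: TemperatureModel):
    """Uncertainty-normalized residuals, one entry per experiment.

    An "experiment" is one titration curve, one dialysis measurement, one
    observed-rate curve or one unwinding-rate determination; each
    contributes the mean of its squared normalized residuals to the
    objective, so a 20-point curve and a single rate measurement weigh the
    same.
    """
    out = []
    for iso, weights in dataset.isotherms:
        p = _scale_params(params, temp_model.multiplier(iso.condition.temperature))
        pred = model_isotherm(p, iso.condition, iso.conc, weights)
        sem = iso.sem if iso.sem is not None else np.full_like(iso.signal, 0.02)
        sem = np.where(sem > 0, sem, 0.02)
        out.append(("isotherms", (pred - iso.signal) / sem))
    for m, stderr in dataset.dialysis:
        pred = predict_dialysis_count(
            params, ExperimentalCondition(), m.protein, m.ligand_initial
        )
        out.append(("dialysis", np.array([(pred - dialysis_bound_count(m)) / stderr])))
    for curve in dataset.kobs_curves:
        p = _scale_params(params, temp_model.multiplier(curve.condition.temperature))
        idx = 0 if curve.phase == "fast" else 1
        pred = np.array(
            [
                biexp_rates(p, replace(curve.condition, ligand_conc=c))[idx]
                for c in curve.conc
            ]
        )
        sem = curve.stderr if curve.stderr is not None else 0.05 * np.abs(curve.k_obs)
        sem = np.where(sem > 0, sem, np.maximum(0.05 * np.abs(curve.k_obs), 1e-6))
        out.append(("kobs", (pred - curve.k_obs) / sem))
    for rec in dataset.unwinding:
        p = _scale_params(params, temp_model.multiplier(rec.condition.temperature))
        pred = steady_unwinding_rate(p, rec.condition)
        sem = rec.stderr if rec.stderr > 0 else max(0.03 * abs(rec.rate), 1e-6)
        out.append(("unwinding", np.array([(pred - rec.rate) / sem])))
    return out


def _block_residuals(params, dataset: Dataset, temp_model: TemperatureModel):
    """Per-modality aggregation of the experiment residuals (reporting)."""
    blocks = {}
    for name, r in _experiment_residuals(params, dataset, temp_model):
        blocks.setdefault(name, []).append(r)
    return {k: np.concatenate(v) for k, v in blocks.items()}


def residual_vector(params, dataset, temp_model=TemperatureModel()):
    """Concatenated residuals, scaled so modality blocks weigh equally."""
    blocks = _block_residuals(params, dataset, temp_model)
    parts = [r / np.sqrt(len(r)) for r in blocks.values() if len(r)]
    return np.concatenate(parts) if parts else np.zeros(0)


def objective(params, dataset, temp_model=TemperatureModel()):
    """Per-block-normalized sum of squared residuals (≥ 0).

    Deterministic in (params, dataset, temp_model) and invariant to record
    order.  Prediction failures map to a large penalty.
    """
    try:
        r = residual_vector(params, dataset, temp_model)
    except Exception:  # noqa: BLE001 - any model failure is a bad parameter set
        return 1e12
    if not np.all(np.isfinite(r)):
        return 1e12
    return float(r @ r)


# ---------------------------------------------------------------------------
# Parameter vector packing
# ---------------------------------------------------------------------------

def _theta_to_params(theta_log, free_names, base: ModelParameters) -> ModelParameters:
    updates = {}
    for x, name in zip(theta_log, free_names):
        mag = np.exp(x)
        updates[name] = -mag if name in _NEGATIVE_PARAMS else mag
    return base.replace(**updates)


def _params_to_theta(params: ModelParameters, free_names):
    out = []
    for name in free_names:
        val = getattr(params, name)
        mag = abs(val)
        lo, _ = DEFAULT_BOUNDS[name]
        out.append(np.log(max(mag, lo)))
    return np.array(out)


def informed_starts(dataset: Dataset, n_weak: int = 4) -> list[ModelParameters]:
    """Initialization candidates derived from per-modality quick fits.

    This is the initialization a practitioner would use: strong/weak
    dissociation constants from a double-Hill fit of the base-condition
    isotherm, catalytic rates from the slope/intercept of the fast
    observed-rate curve, auxiliary rates from the slow-curve level, and the
    catalysis rate from the saturating unwinding rate.  The cooperativity
    factor and transfer rate are poorly constrained by any single modality,
    so a small grid of plausible magnitudes is returned (one candidate
    per combination).
    """
    from .equilibrium import fit_double_hill

    bnd = DEFAULT_BOUNDS

    def clip(name, value):
        lo, hi = bnd[name]
        return float(np.clip(abs(value), lo, hi))

    # strong/weak phase constants from the base-condition isotherm
    Ksd, Kw_app = 30.0, 400.0
    if dataset.isotherms:
        base_iso = min(
            dataset.isotherms,
            key=lambda rec: (rec[0].condition.adenosine, rec[0].condition.nacl),
        )[0]
        try:
            hill = fit_double_hill(base_iso)
            Ksd, Kw_app = hill.Ks, hill.Kw
        except Exception:  # noqa: BLE001 - fall back to generic magnitudes
            pass

    # catalytic rates from the fast observed-rate curve
    ks_on0, ks_off0 = None, None
    fast = [c for c in dataset.kobs_curves if c.phase == "fast"]
    slow = [c for c in dataset.kobs_curves if c.phase == "slow"]
    if fast:
        slope, intercept = np.polyfit(fast[0].conc, fast[0].k_obs, 1)
        if slope > 0:
            ks_on0 = slope
            ks_off0 = max(intercept, slope * Ksd)
    if ks_on0 is None:
        ks_on0, ks_off0 = 1.0, 1.0 * Ksd
    slow_level = float(np.median(slow[0].k_obs)) if slow else 10.0 * ks_off0

    vmax0 = 1000.0
    if dataset.unwinding:
        top = max(dataset.unwinding, key=lambda r: r.rate)
        # rate_bp ≈ bp_per_atp · n_cat · vmax at saturation
        vmax0 = max(top.rate, 10.0)

    starts = []
    for a0 in (8.0, 30.0, 90.0):
        Kd_micro = Kw_app * a0 ** ((n_weak - 1) / n_weak)
        kw_off0 = 2.0 * slow_level
        kw_on0 = kw_off0 / Kd_micro
        for ktr0 in (3.0 * ks_off0, 30.0 * ks_off0):
            starts.append(
                ModelParameters(
                    ks_on=clip("ks_on", ks_on0),
                    ks_off=clip("ks_off", ks_off0),
                    kw_on_intercept=clip("kw_on_intercept", kw_on0),
                    kw_on_slope_ado=-clip("kw_on_slope_ado", 0.4 * kw_on0),
                    kw_off_intercept=clip("kw_off_intercept", kw_off0),
                    kw_off_slope_nacl=-clip("kw_off_slope_nacl", 0.3 * kw_off0 / 225.0),
                    ktr_fwd_intercept=clip("ktr_fwd_intercept", ktr0),
                    ktr_fwd_slope_nacl=-clip("ktr_fwd_slope_nacl", 0.5 * ktr0 / 300.0),
                    ktr_rev=clip("ktr_rev", 0.1 * ktr0),
                    coop_a=clip("coop_a", a0),
                    vmax=clip("vmax", vmax0),
                    n_weak_sites=n_weak,
                )
            )
    return starts


@dataclass
class GlobalFitResult:
    params: ModelParameters
    theta: dict
    objective: float
    block_residuals: dict
    n_starts: int
    start_objectives: list
    free_names: tuple
    success: bool = True


def _identifiable_free_names(dataset: Dataset):
    conds = dataset.conditions()
    free = list(FREE_PARAMETER_NAMES)
    n_ado = len({c.adenosine for c in conds})
    n_nacl = len({c.nacl for c in conds})
    if n_ado < 2:
        warnings.warn(
            "dataset varies adenosine at fewer than 2 levels: fixing the "
            "adenosine slope to 0",
            stacklevel=3,
        )
        free.remove("kw_on_slope_ado")
    if n_nacl < 2:
        warnings.warn(
            "dataset varies NaCl at fewer than 2 levels: fixing the NaCl "
            "slopes to 0",
            stacklevel=3,
        )
        free.remove("kw_off_slope_nacl")
        free.remove("ktr_fwd_slope_nacl")
    return tuple(free)


def _local_fit(dataset, temp_model, base, free_names, x0, lb, ub, max_nfev=400):
    def resid(x):
        p = _theta_to_params(x, free_names, base)
        try:
            r = residual_vector(p, dataset, temp_model)
        except Exception:  # noqa: BLE001
            return np.full(max(dataset.n_records(), 1), 1e6)
        return np.where(np.isfinite(r), r, 1e6)

    sol = least_squares(
        resid, np.clip(x0, lb, ub), bounds=(lb, ub),
        method="trf", x_scale="jac", max_nfev=max_nfev,
    )
    return sol


def run_global_fit(
    dataset: Dataset,
    bounds: dict | None = None,
    n_starts: int = 20,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    temp_model: TemperatureModel = TemperatureModel(),
    extra_starts: list | None = None,
    auto_informed: bool = True,
    max_nfev: int = 400,
) -> GlobalFitResult:
    """Multi-start bounded least squares over the free parameters.

    Data-informed starting points (:func:`informed_starts`) are tried
    first, then optional ``extra_starts`` (ModelParameters), then
    log-uniform random starts over the box bounds up to ``n_starts`` in
    total (deterministic under ``seed``).  Slope parameters are fitted as
    magnitudes with their "decreasing" sign fixed.  Datasets that do not
    vary adenosine or NaCl get the corresponding slopes fixed at zero with
    a warning.
    """
    if dataset.n_records() == 0:
        raise FitError("empty dataset")
    base = base_params or ModelParameters(
        kw_on_slope_ado=0.0, kw_off_slope_nacl=0.0, ktr_fwd_slope_nacl=0.0
    )
    free_names = _identifiable_free_names(dataset)
    for name in set(FREE_PARAMETER_NAMES) - set(free_names):
        base = base.replace(**{name: 0.0})
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    lb = np.array([np.log(box[n][0]) for n in free_names])
    ub = np.array([np.log(box[n][1]) for n in free_names])

    rng = np.random.default_rng(seed)
    candidates = list(extra_starts or [])
    if auto_informed:
        try:
            candidates = informed_starts(dataset, n_weak=base.n_weak_sites) + candidates
        except Exception:  # noqa: BLE001 - informed starts are best-effort
            pass
    starts = [_params_to_theta(p0, free_names) for p0 in candidates]
    while len(starts) < n_starts:
        starts.append(lb + rng.uniform(size=len(free_names)) * (ub - lb))

    best = None
    outcomes = []
    for x0 in starts:
        try:
            sol = _local_fit(dataset, temp_model, base, free_names, x0, lb, ub, max_nfev)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            outcomes.append(np.inf)
            continue
        outcomes.append(float(2.0 * sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all optimization starts failed")
    # polish the winning start with a larger evaluation budget
    polished = _local_fit(
        dataset, temp_model, base, free_names, best.x, lb, ub, max_nfev=4 * max_nfev
    )
    if polished.cost < best.cost:
        best = polished
    params = _theta_to_params(best.x, free_names, base)
    blocks = _block_residuals(params, dataset, temp_model)
    return GlobalFitResult(
        params=params,
        theta={n: getattr(params, n) for n in free_names},
        objective=float(2.0 * best.cost),
        block_residuals={k: float(v @ v / len(v)) for k, v in blocks.items()},
        n_starts=len(starts),
        start_objectives=outcomes,
        free_names=free_names,
    )


# ---------------------------------------------------------------------------
# Bootstrap Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    n_replicates: int
    replicates: list  # per-replicate theta dicts (converged only)
    summary: dict  # name -> (mean, sd) of the parameter histogram
    convergence_fraction: float
    seed: int = 0


def _perturb_dataset(dataset: Dataset, rng, width: float = 1.0) -> Dataset:
    new = Dataset()
    for iso, weights in dataset.isotherms:
        sem = iso.sem if iso.sem is not None else np.full_like(iso.signal, 0.02)
        sig = iso.signal + width * sem * rng.standard_normal(len(iso.signal))
        new.isotherms.append(
            (BindingIsotherm(iso.conc.copy(), sig, sem.copy(), iso.condition), weights)
        )
    for m, stderr in dataset.dialysis:
        shift = width * stderr * m.protein / 2.0 * rng.standard_normal()
        new.dialysis.append(
            (
                DialysisMeasurement(m.ligand_initial, max(m.ligand_final + shift, 0.0), m.protein),
                stderr,
            )
        )
    for c in dataset.kobs_curves:
        sem = c.stderr if c.stderr is not None else 0.05 * np.abs(c.k_obs)
        kv = c.k_obs + width * sem * rng.standard_normal(len(c.k_obs))
        new.kobs_curves.append(
            KobsCurve(c.conc.copy(), np.clip(kv, 1e-9, None), sem.copy(), c.condition, c.phase)
        )
    for u in dataset.unwinding:
        new.unwinding.append(
            UnwindingRateRecord(
                max(u.rate + width * u.stderr * rng.standard_normal(), 0.0),
                u.stderr,
                u.condition,
            )
        )
    return new


def bootstrap(
    dataset: Dataset,
    truth_fit: GlobalFitResult,
    n: int = 100,
    seed: int = 0,
    width: float = 1.0,
    temp_model: TemperatureModel = TemperatureModel(),
    max_nfev: int = 200,
) -> BootstrapResult:
    """Parametric bootstrap: perturb every record by its uncertainty, refit.

    Each replicate is refitted locally from the point estimate (the
    standard warm start for bootstrap refits).  Failed replicates are
    recorded and excluded from the histograms; the per-parameter Gaussian
    summary is the (mean, sd) of the converged replicate values.
    """
    rng = np.random.default_rng(seed)
    free_names = truth_fit.free_names
    base = truth_fit.params
    lb = np.array([np.log(DEFAULT_BOUNDS[nm][0]) for nm in free_names])
    ub = np.array([np.log(DEFAULT_BOUNDS[nm][1]) for nm in free_names])
    x_hat = _params_to_theta(truth_fit.params, free_names)
    replicates = []
    failures = 0
    for _ in range(n):
        pert = _perturb_dataset(dataset, rng, width)
        try:
            sol = _local_fit(pert, temp_model, base, free_names, x_hat, lb, ub, max_nfev)
            p = _theta_to_params(sol.x, free_names, base)
            replicates.append({nm: getattr(p, nm) for nm in free_names})
        except Exception:  # noqa: BLE001
            failures += 1
    summary = {}
    for nm in free_names:
        vals = np.array([r[nm] for r in replicates])
        summary[nm] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return BootstrapResult(
        n_replicates=n,
        replicates=replicates,
        summary=summary,
        convergence_fraction=len(replicates) / n if n else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Weak-site-count model selection
# ---------------------------------------------------------------------------

def _aicc(rss_like: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss_like, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_weak_site_count(
    dataset: Dataset,
    candidates=(2, 3, 4, 5, 6),
    n_starts: int = 8,
    seed: int = 0,
    temp_model: TemperatureModel = TemperatureModel(),
    max_nfev: int = 300,
):
    """Refit the scheme with different auxiliary-site counts; pick by AICc.

    Equilibrium isotherms (and dialysis counts) are the discriminating
    modality: too few sites cannot reproduce the cooperative weak phase,
    too many overshoot the saturating stoichiometry.  Returns
    ``(best_count, table)`` where the table maps candidate → (objective,
    AICc).
    """
    if not dataset.isotherms:
        raise InvalidArgumentError("model selection requires equilibrium isotherms")
    n = dataset.n_records()
    table = {}
    best_count, best_aicc = None, np.inf
    for n_weak in candidates:
        base = ModelParameters(n_weak_sites=n_weak)
        fit = run_global_fit(
            dataset,
            n_starts=n_starts,
            seed=seed,
            base_params=base,
            temp_model=temp_model,
            max_nfev=max_nfev,
        )
        k = len(fit.free_names)
        aicc = _aicc(fit.objective, n, k)
        table[n_weak] = {"objective": fit.objective, "aicc": aicc}
        if aicc < best_aicc:
            best_count, best_aicc = n_weak, aicc
    return best_count, table
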