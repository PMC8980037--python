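"""Kinetic scheme of ATP binding, transfer and hydrolysis by RecBCD.

The enzyme is modelled as a lattice of two classes of nucleotide-binding
sites: ``n_cat`` identical, non-cooperative catalytic sites (RecB and RecD
motors) and ``n_weak`` cooperative auxiliary sites (RecC).  A state is a
pair ``(w, c)`` counting ATP molecules bound to the auxiliary and catalytic
sites respectively.  Transitions are:

* catalytic binding/unbinding, sequential macroscopic rates ``ks_on*T`` /
  ``ks_off`` (no statistical multiplicity factors, so the stationary weights
  reproduce the macroscopic binding polynomial);
* auxiliary binding at ``kw_on*T`` for the first molecule and ``a*kw_on*T``
  for every subsequent one (positive cooperativity enters through the
  on-rate only), unbinding at ``kw_off``;
* direct transfer of a bound ATP from an auxiliary to an empty catalytic
  site at ``ktr_fwd``, reverse at ``ktr_rev``;
* optionally, hydrolysis at each occupied catalytic site, which consumes
  the bound ATP and powers duplex unwinding.

Auxiliary association/dissociation and the transfer rate respond linearly
to adenosine (a competitor for the auxiliary sites) and NaCl; see
:func:`resolve_rates`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidArgumentError, NumericalError

__all__ = [
    "ModelParameters",
    "ExperimentalCondition",
    "EffectiveRates",
    "StateSpace",
    "KineticTrajectory",
    "enumerate_states",
    "resolve_rates",
    "polynomial_coefficients",
    "binding_polynomial",
    "mean_occupancy",
    "site_occupancies",
    "build_generator",
    "stationary_distribution",
    "simulate_binding_kinetics",
    "simulate_unwinding",
    "steady_unwinding_rate",
    "relaxation_spectrum",
    "relaxation_modes",
    "biexp_rates",
]

# Default mechanochemical coupling: the motor consumes two ATP per base pair
# unwound, i.e. 0.5 bp advanced per hydrolysis event.
DEFAULT_BP_PER_ATP = 0.5


@dataclass(frozen=True)
class ExperimentalCondition:
    """Solution conditions of a measurement.

    ligand_conc : ATP or mant-nucleotide concentration (µM)
    nacl        : NaCl concentration (mM)
    adenosine   : adenosine concentration (mM); blocks the auxiliary sites
    temperature : °C
    """

    ligand_conc: float = 0.0
    nacl: float = 75.0
    adenosine: float = 0.0
    temperature: float = 25.0

    def __post_init__(self):
        for name in ("ligand_conc", "nacl", "adenosine"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ModelParameters:
    """Microscopic parameters of the scheme.

    Rates are s⁻¹, association rates µM⁻¹·s⁻¹.  The auxiliary on-rate,
    off-rate and forward transfer rate are linear in adenosine (mM) and
    NaCl (mM) respectively and clamped at zero:

        kw_on   = max(0, kw_on_intercept  + kw_on_slope_ado  * [adenosine])
        kw_off  = max(0, kw_off_intercept + kw_off_slope_nacl * [NaCl])
        ktr_fwd = max(0, ktr_fwd_intercept + ktr_fwd_slope_nacl * [NaCl])

    ``coop_a`` multiplies the auxiliary on-rate for the second and later
    bindings.  ``vmax`` is the hydrolysis rate per occupied catalytic site.
    """

    ks_on: float = 5.0
    ks_off: float = 150.0
    kw_on_intercept: float = 0.3
    kw_on_slope_ado: float = -0.12
    kw_off_intercept: float = 2961.0
    kw_off_slope_nacl: float = -4.125
    ktr_fwd_intercept: float = 3900.0
    ktr_fwd_slope_nacl: float = -12.0
    ktr_rev: float = 300.0
    coop_a: float = 60.0
    vmax: float = 1900.0
    n_weak_sites: int = 4
    n_cat_sites: int = 2

    def __post_init__(self):
        if self.coop_a <= 0:
            raise InvalidArgumentError("coop_a must be > 0")
        if self.n_weak_sites < 0 or self.n_cat_sites < 1:
            raise InvalidArgumentError(
                "need n_weak_sites >= 0 and n_cat_sites >= 1"
            )
        for name in ("ks_on", "ks_off", "ktr_rev", "vmax"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls(**json.loads(text))

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EffectiveRates:
    """Condition-resolved rate constants (all clamped nonnegative)."""

    ks_on: float
    ks_off: float
    kw_on: float
    kw_off: float
    ktr_fwd: float
    ktr_rev: float
    coop_a: float
    vmax: float

    @property
    def Ks(self) -> float:
        """Catalytic association constant k_s⁺/k_s⁻ (µM⁻¹)."""
        return self.ks_on / self.ks_off if self.ks_off > 0 else np.inf

    @property
    def Kw(self) -> float:
        """Auxiliary association constant k_w⁺/k_w⁻ (µM⁻¹)."""
        return self.kw_on / self.kw_off if self.kw_off > 0 else np.inf


def resolve_rates(
    params: ModelParameters, condition: ExperimentalCondition
) -> EffectiveRates:
    """Evaluate the condition-linear rate laws at a given condition.

    Negative linear extrapolations are clamped to zero, which encodes the
    "nonnegative linear decreasing" dependence of the auxiliary-site rates
    on adenosine and salt.
    """
    kw_on = max(0.0, params.kw_on_intercept + params.kw_on_slope_ado * condition.adenosine)
    kw_off = max(0.0, params.kw_off_intercept + params.kw_off_slope_nacl * condition.nacl)
    ktr_fwd = max(0.0, params.ktr_fwd_intercept + params.ktr_fwd_slope_nacl * condition.nacl)
    return EffectiveRates(
        ks_on=params.ks_on,
        ks_off=params.ks_off,
        kw_on=kw_on,
        kw_off=kw_off,
        ktr_fwd=ktr_fwd,
        ktr_rev=params.ktr_rev,
        coop_a=params.coop_a,
        vmax=params.vmax,
    )


@dataclass(frozen=True)
class StateSpace:
    """Lexicographically ordered enumeration of occupancy states (w, c)."""

    n_weak: int
    n_cat: int
    states: tuple = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "states",
            tuple(
                (w, c)
                for w in range(self.n_weak + 1)
                for c in range(self.n_cat + 1)
            ),
        )

    def __len__(self):
        return len(self.states)

    def index(self, w: int, c: int) -> int:
        return w * (self.n_cat + 1) + c

    @property
    def labels(self):
        return [f"w{w}c{c}" for w, c in self.states]

    @property
    def bound_counts(self) -> np.ndarray:
        """w + c per state (the FRET/fluorescence observable weight)."""
        return np.array([w + c for w, c in self.states], dtype=float)


def enumerate_states(n_weak: int, n_cat: int) -> StateSpace:
    """All (auxiliary, catalytic) occupancy pairs, lexicographic order."""
    if n_weak < 0 or n_cat < 1:
        raise InvalidArgumentError("need n_weak >= 0 and n_cat >= 1")
    return StateSpace(n_weak=n_weak, n_cat=n_cat)


# ---------------------------------------------------------------------------
# Binding polynomial
# ---------------------------------------------------------------------------

def _weak_chain(Kw, a, n_weak):
    # statistical weight of w auxiliary-bound ligands: a^{max(w-1,0)} Kw^w
    return [a ** max(w - 1, 0) * Kw**w for w in range(n_weak + 1)]


def _strong_chain(Ks, n_cat):
    # sequential macroscopic weights: Ks^c
    return [Ks**c for c in range(n_cat + 1)]


def polynomial_coefficients(Ks, Kw, a, n_weak=4, n_cat=2, form="product"):
    """Coefficients of the binding polynomial Ψ(T) = Σ_k coeff_k · T^k.

    ``form="product"`` is the canonical product of the independent weak and
    strong chains (no cooperativity between the site classes).
    ``form="as_printed"`` reproduces a published coefficient set for the
    (4 weak, 2 catalytic) scheme that differs from the product form in the
    T⁴ and T⁵ terms; it is kept for comparison and never reconciled
    silently.

    Arithmetic is generic: with ``fractions.Fraction`` inputs the
    coefficients are exact.
    """
    if form == "product":
        weak = _weak_chain(Kw, a, n_weak)
        strong = _strong_chain(Ks, n_cat)
        coeffs = [0 * (Ks + Kw)] * (n_weak + n_cat + 1)
        for w, ww in enumerate(weak):
            for c, sw in enumerate(strong):
                coeffs[w + c] = coeffs[w + c] + ww * sw
        return coeffs
    if form == "as_printed":
        if n_weak != 4 or n_cat != 2:
            raise InvalidArgumentError(
                "as_printed form is defined only for 4 weak + 2 catalytic sites"
            )
        return [
            1 + 0 * Ks,
            Ks + Kw,
            Ks**2 + Ks * Kw + a * Kw**2,
            Ks**2 * Kw + a * Ks * Kw**2 + a**2 * Kw**3,
            a * Ks**2 * Kw**2 + a * Ks * Kw**3 + a**3 * Kw**4,
            a**2 * Ks * Kw**3 + a**3 * Ks * Kw**4,
            a**3 * Ks**2 * Kw**4,
        ]
    raise InvalidArgumentError(f"unknown polynomial form {form!r}")


def binding_polynomial(Ks, Kw, a, T, form="product", n_weak=4, n_cat=2):
    """Binding polynomial Ψ(T); Ψ(0) = 1 always."""
    _check_nonneg(Ks=Ks, Kw=Kw, a=a)
    coeffs = polynomial_coefficients(Ks, Kw, a, n_weak, n_cat, form)
    return _horner(coeffs, T)


def mean_occupancy(Ks, Kw, a, T, form="product", n_weak=4, n_cat=2):
    """Mean number of bound ligands, T·Ψ'(T)/Ψ(T) = ∂lnΨ/∂lnT."""
    _check_nonneg(Ks=Ks, Kw=Kw, a=a)
    coeffs = polynomial_coefficients(Ks, Kw, a, n_weak, n_cat, form)
    num = _horner([k * ck for k, ck in enumerate(coeffs)], T)
    den = _horner(coeffs, T)
    return num / den


def site_occupancies(Ks, Kw, a, T, n_weak=4, n_cat=2):
    """Mean auxiliary and catalytic occupancies (⟨w⟩, ⟨c⟩) separately.

    Computed by direct enumeration of the product-form state weights
    Ks^c · a^{max(w-1,0)} · Kw^w · T^{w+c}.
    """
    _check_nonneg(Ks=Ks, Kw=Kw, a=a)
    T = np.asarray(T, dtype=float)
    weak = _weak_chain(Kw, a, n_weak)
    strong = _strong_chain(Ks, n_cat)
    psi = np.zeros_like(T, dtype=float)
    mw = np.zeros_like(T, dtype=float)
    mc = np.zeros_like(T, dtype=float)
    for w, ww in enumerate(weak):
        for c, sw in enumerate(strong):
            weight = ww * sw * T ** (w + c)
            psi = psi + weight
            mw = mw + w * weight
            mc = mc + c * weight
    return mw / psi, mc / psi


def _horner(coeffs, T):
    acc = 0.0 * np.asarray(T) if isinstance(T, np.ndarray) else 0 * coeffs[0]
    for ck in reversed(coeffs):
        acc = acc * T + ck
    return acc


def _check_nonneg(**kwargs):
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise InvalidArgumentError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Generator and dynamics
# ---------------------------------------------------------------------------

def build_generator(
    space: StateSpace,
    rates: EffectiveRates,
    T: float,
    cycle_consistent: bool = False,
) -> np.ndarray:
    """Transition-rate matrix Q with Q[i, j] = rate from state i to state j.

    Rows sum to zero; probabilities evolve as dp/dt = Qᵀ p.  With
    ``cycle_consistent=True`` the reverse transfer rate on each edge is
    derived from detailed balance against the equilibrium state weights
    (ktr_fwd/ktr_rev = Ks/(a^{min(w-1,1)}·Kw) on the cycle entered from
    auxiliary occupancy w), so the stationary distribution matches the
    binding polynomial exactly; otherwise the constant ``ktr_rev`` is used.
    """
    n = len(space)
    Q = np.zeros((n, n))
    a = rates.coop_a
    for i, (w, c) in enumerate(space.states):
        if w < space.n_weak:
            Q[i, space.index(w + 1, c)] += rates.kw_on * T * (a if w >= 1 else 1.0)
        if w > 0:
            Q[i, space.index(w - 1, c)] += rates.kw_off
        if c < space.n_cat:
            Q[i, space.index(w, c + 1)] += rates.ks_on * T
        if c > 0:
            Q[i, space.index(w, c - 1)] += rates.ks_off
        if w > 0 and c < space.n_cat:
            Q[i, space.index(w - 1, c + 1)] += rates.ktr_fwd
        if w < space.n_weak and c > 0:
            if cycle_consistent:
                # reverse of the transfer edge entered from occupancy w+1
                if rates.ks_on > 0 and rates.kw_off > 0:
                    ratio = (a ** min(w, 1)) * rates.Kw / rates.Ks
                    Q[i, space.index(w + 1, c - 1)] += rates.ktr_fwd * ratio
            else:
                Q[i, space.index(w + 1, c - 1)] += rates.ktr_rev
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _hydrolysis_rates(space: StateSpace, vmax: float, catalysis: str) -> np.ndarray:
    """Per-state hydrolysis rate h(w, c)."""
    if catalysis == "proportional":
        return np.array([vmax * c for _, c in space.states], dtype=float)
    if catalysis == "any":
        return np.array([vmax * (c >= 1) for _, c in space.states], dtype=float)
    raise InvalidArgumentError(f"unknown catalysis mode {catalysis!r}")


def _augment_with_catalysis(
    Q: np.ndarray, space: StateSpace, vmax: float, catalysis: str
) -> np.ndarray:
    """Add the hydrolysis transitions (w, c) -> (w, c-1) to a generator."""
    Qh = Q.copy()
    h = _hydrolysis_rates(space, vmax, catalysis)
    for i, (w, c) in enumerate(space.states):
        if c > 0 and h[i] > 0:
            j = space.index(w, c - 1)
            Qh[i, i] -= h[i]
            Qh[i, j] += h[i]
    return Qh


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary probability vector of a generator (πQ = 0, Σπ = 1)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.linalg.norm(Q.T @ pi)
    scale = max(1.0, np.abs(Q).max())
    if resid > 1e-8 * scale or np.any(pi < -1e-8):
        raise NumericalError(
            "stationary distribution ill-conditioned (reducible generator?)",
            diagnostics={"residual": float(resid), "min": float(pi.min())},
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class KineticTrajectory:
    """Time course of the occupancy distribution and its observable."""

    time: np.ndarray
    probabilities: np.ndarray  # (n_times, n_states)
    space: StateSpace
    hydrolysis: np.ndarray | None = None  # cumulative ATP consumed

    @property
    def observable(self) -> np.ndarray:
        """Mean number of bound ligands (weights the signal in FRET assays)."""
        return self.probabilities @ self.space.bound_counts

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.time}
        for j, label in enumerate(self.space.labels):
            data[label] = self.probabilities[:, j]
        data["observable"] = self.observable
        if self.hydrolysis is not None:
            data["hydrolysis_atp"] = self.hydrolysis
        return pd.DataFrame(data)


def _solve_linear_master(M: np.ndarray, y0: np.ndarray, t_eval: np.ndarray):
    sol = solve_ivp(
        lambda t, y: M @ y,
        (t_eval[0], t_eval[-1]),
        y0,
        method="BDF",
        t_eval=t_eval,
        jac=lambda t, y: M,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise NumericalError(
            "master-equation integration failed",
            diagnostics={"message": sol.message},
        )
    return sol.y.T


def simulate_binding_kinetics(
    params: ModelParameters,
    condition: ExperimentalCondition,
    t_max: float,
    n_points: int = 200,
    cycle_consistent: bool = False,
) -> KineticTrajectory:
    """Transient binding after mixing apo enzyme with ligand at t = 0."""
    if t_max <= 0:
        raise InvalidArgumentError("t_max must be > 0")
    space = enumerate_states(params.n_weak_sites, params.n_cat_sites)
    rates = resolve_rates(params, condition)
    Q = build_generator(space, rates, condition.ligand_conc, cycle_consistent)
    t = np.linspace(0.0, t_max, n_points)
    p0 = np.zeros(len(space))
    p0[space.index(0, 0)] = 1.0
    P = _solve_linear_master(Q.T, p0, t)
    return KineticTrajectory(time=t, probabilities=P, space=space)


def simulate_unwinding(
    params: ModelParameters,
    condition: ExperimentalCondition,
    t_max: float = 30.0,
    n_points: int = 300,
    bp_per_atp: float = DEFAULT_BP_PER_ATP,
    catalysis: str = "proportional",
    fit_fraction: float = 0.8,
) -> tuple[KineticTrajectory, float]:
    """ATP-driven unwinding: cumulative hydrolysis trace and its rate.

    Hydrolysis consumes the ATP at an occupied catalytic site; unwinding is
    proportional to hydrolysis with ``bp_per_atp`` base pairs advanced per
    ATP.  The rate is the slope of a linear fit over the final
    ``fit_fraction`` of the trace (the quasi-steady portion) scaled by
    ``bp_per_atp``.
    """
    if t_max <= 0:
        raise InvalidArgumentError("t_max must be > 0")
    space = enumerate_states(params.n_weak_sites, params.n_cat_sites)
    rates = resolve_rates(params, condition)
    Q = build_generator(space, rates, condition.ligand_conc)
    Qh = _augment_with_catalysis(Q, space, rates.vmax, catalysis)
    h = _hydrolysis_rates(space, rates.vmax, catalysis)
    n = len(space)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = Qh.T
    M[n, :n] = h
    y0 = np.zeros(n + 1)
    y0[space.index(0, 0)] = 1.0
    t = np.linspace(0.0, t_max, n_points)
    Y = _solve_linear_master(M, y0, t)
    traj = KineticTrajectory(
        time=t, probabilities=Y[:, :n], space=space, hydrolysis=Y[:, n]
    )
    tail = t >= (1.0 - fit_fraction) * t_max
    slope = np.polyfit(t[tail], Y[tail, n], 1)[0]
    return traj, float(slope * bp_per_atp)


def steady_unwinding_rate(
    params: ModelParameters,
    condition: ExperimentalCondition,
    bp_per_atp: float = DEFAULT_BP_PER_ATP,
    catalysis: str = "proportional",
) -> float:
    """Stationary unwinding rate (bp·s⁻¹) from the catalysis-augmented scheme.

    Equivalent to the long-time slope of :func:`simulate_unwinding` but
    computed from the stationary distribution, which is orders of magnitude
    faster inside an optimization loop.
    """
    space = enumerate_states(params.n_weak_sites, params.n_cat_sites)
    rates = resolve_rates(params, condition)
    Q = build_generator(space, rates, condition.ligand_conc)
    Qh = _augment_with_catalysis(Q, space, rates.vmax, catalysis)
    h = _hydrolysis_rates(space, rates.vmax, catalysis)
    if np.abs(Qh).max() == 0:
        return 0.0
    pi = stationary_distribution(Qh)
    return float(bp_per_atp * h @ pi)


def relaxation_spectrum(
    params: ModelParameters, condition: ExperimentalCondition
) -> tuple[np.ndarray, np.ndarray]:
    """All decaying modes of the binding observable: (rates, amplitudes).

    The observable relaxes from the apo state as Σ_i a_i·exp(−λ_i·t) plus
    its equilibrium value; returns the λ_i > 0 with their amplitudes
    (real parts; complex pairs sum to real contributions).
    """
    space = enumerate_states(params.n_weak_sites, params.n_cat_sites)
    rates = resolve_rates(params, condition)
    Q = build_generator(space, rates, condition.ligand_conc)
    if np.abs(Q).max() == 0:
        return np.array([]), np.array([])
    w_counts = space.bound_counts
    lam, V = np.linalg.eig(Q.T)
    p0 = np.zeros(len(space))
    p0[space.index(0, 0)] = 1.0
    try:
        coef = np.linalg.solve(V, p0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise NumericalError("generator eigendecomposition failed") from exc
    amps = (w_counts @ V) * coef
    scale = max(np.abs(lam).max(), 1.0)
    keep = -lam.real > 1e-10 * scale
    return -lam[keep].real, amps[keep].real


def biexp_rates(
    params: ModelParameters, condition: ExperimentalCondition
) -> tuple[float, float]:
    """Two-exponential reduction (k_fast, k_slow) of the binding relaxation.

    The full master-equation observable decays as a sum over all modes; a
    stopped-flow analysis summarizes it by a double exponential.  Here the
    double exponential is obtained in closed form by matching the first
    four time-moments of the decay (a Prony/Padé reduction), which is a
    smooth function of the model parameters — unlike picking the two
    largest-amplitude eigenmodes, whose identity switches discontinuously.
    Exact for genuinely biexponential spectra; degenerate (effectively
    single-phase) spectra return the equivalent single rate twice.
    """
    lams, amps = relaxation_spectrum(params, condition)
    if lams.size == 0:
        return 0.0, 0.0
    amp_tot = float(np.sum(amps))
    mu1 = float(np.sum(amps / lams))
    if mu1 == 0 or amp_tot == 0:
        return 0.0, 0.0
    k_single = abs(amp_tot / mu1)

    # Laplace transform of the decay, M(s) = Σ a_i/(λ_i + s), interpolated
    # by a [1/2] rational function whose poles are the two effective rates.
    s_pts = k_single * np.array([0.2, 1.0, 5.0, 25.0])
    M = np.array([np.sum(amps / (lams + s)) for s in s_pts])
    # M(s)·(c0 + c1·s + s²) = b0 + b1·s  →  linear in (b0, b1, c0, c1)
    A = np.column_stack([np.ones(4), s_pts, -M, -M * s_pts])
    rhs = M * s_pts**2
    try:
        coef, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return k_single, k_single
    b0, b1, c0, c1 = coef
    disc = c1 * c1 - 4.0 * c0
    if not np.isfinite(disc) or disc < 0:
        return k_single, k_single
    k1 = (c1 + np.sqrt(disc)) / 2.0
    k2 = (c1 - np.sqrt(disc)) / 2.0
    if k1 <= 0 or k2 <= 0:
        return k_single, k_single
    k_pair = sorted((float(k1), float(k2)), reverse=True)
    return k_pair[0], k_pair[1]


def relaxation_modes(
    params: ModelParameters,
    condition: ExperimentalCondition,
    n_modes: int = 2,
) -> list[tuple[float, float]]:
    """Dominant relaxation rates of the binding observable.

    Spectrally decomposes the master equation started from the apo state:
    the observable relaxes as a sum of exponentials with rates −λ_m.  The
    ``n_modes`` modes with the largest amplitudes are returned as
    ``(k_obs, amplitude)`` pairs sorted fast to slow.  These are the model's
    prediction for the phases seen in stopped-flow mixing experiments.
    """
    space = enumerate_states(params.n_weak_sites, params.n_cat_sites)
    rates = resolve_rates(params, condition)
    Q = build_generator(space, rates, condition.ligand_conc)
    if np.abs(Q).max() == 0:
        return [(0.0, 0.0)] * n_modes
    w_counts = space.bound_counts
    lam, V = np.linalg.eig(Q.T)
    p0 = np.zeros(len(space))
    p0[space.index(0, 0)] = 1.0
    try:
        coef = np.linalg.solve(V, p0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise NumericalError("generator eigendecomposition failed") from exc
    amps = (w_counts @ V) * coef
    scale = np.abs(lam).max()
    modes = [
        (float(-lam[m].real), float(-amps[m].real))
        for m in range(len(lam))
        if -lam[m].real > 1e-10 * max(scale, 1.0)
    ]
    modes.sort(key=lambda ka: abs(ka[1]), reverse=True)
    top = modes[:n_modes]
    top.sort(key=lambda ka: ka[0], reverse=True)
    while len(top) < n_modes:
        top.append((0.0, 0.0))
    return top
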