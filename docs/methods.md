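# Methods

## The kinetic scheme

`recbcd_kinetics` models a helicase (RecBCD) that carries two classes of
nucleotide-binding sites: `n_cat = 2` identical, non-cooperative catalytic
sites (the RecB and RecD motor ATPases) and `n_weak = 4` cooperative
auxiliary sites (RecC) that act as an ATP buffer.  A state of the enzyme is
the pair `(w, c)` of ATP molecules bound to auxiliary and catalytic sites.
The elementary transitions are

| transition | rate | notes |
|---|---|---|
| `(w,c) → (w,c+1)` | `ks_on·T` | catalytic binding, sequential macroscopic rate |
| `(w,c) → (w,c−1)` | `ks_off` | catalytic unbinding |
| `(w,c) → (w+1,c)` | `kw_on·T` (first), `a·kw_on·T` (second and later) | cooperative auxiliary binding |
| `(w,c) → (w−1,c)` | `kw_off` | auxiliary unbinding, occupancy-independent |
| `(w,c) → (w−1,c+1)` | `ktr_fwd` | direct transfer of a bound ATP to an empty catalytic site |
| `(w,c) → (w+1,c−1)` | `ktr_rev` | reverse transfer |
| `(w,c) → (w,c−1)` + 1 hydrolysis | `vmax·c` | catalysis; consumes the bound ATP |

with `T` the free ATP (or mant-nucleotide) concentration in µM.  Model
premises: the catalytic sites are identical and non-cooperative; the
auxiliary sites are cooperative through their on-rate only; there is no
allosteric coupling between the two site classes; unwinding is driven by
hydrolysis at the catalytic sites with a fixed mechanochemical coupling of
0.5 bp advanced per ATP consumed (two ATP per bp), configurable.

Macroscopic (sequential) rate constants are used without binomial
multiplicity factors, so that the stationary weights of the binding-only
scheme reproduce the binding polynomial

    Ψ(T) = (1 + Ks·T + Ks²·T²) · (1 + Kw·T + a·Kw²·T² + a²·Kw³·T³ + a³·Kw⁴·T⁴)

with association constants `Ks = ks_on/ks_off`, `Kw = kw_on/kw_off`, and
mean occupancy `⟨n⟩(T) = ∂lnΨ/∂lnT`.  A second coefficient set
(`form="as_printed"`) reproduces a published expansion that differs from
this product form in the T⁴ and T⁵ terms; the two are kept side by side and
never silently reconciled.  The master-equation dynamics are canonical
against the product form: a dedicated test checks, in exact rational
arithmetic, that the product coefficients equal the brute-force sum of
state weights for every state space up to (4 weak, 2 catalytic).

Three rates respond linearly to solution conditions and are clamped at
zero ("nonnegative linear decreasing" laws):

    kw_on(adenosine)  = max(0, β + α·[adenosine mM])     (adenosine blocks the auxiliary sites)
    kw_off(NaCl)      = max(0, δ + γ·[NaCl mM])          (salt strengthens auxiliary binding)
    ktr_fwd(NaCl)     = max(0, κ + ε·[NaCl mM])          (salt slows the transfer step)

The free parameter vector of the global fit is therefore
`{ks_on, ks_off, ktr_rev, a, vmax, α, β, γ, δ, ε, κ}` — eleven parameters.

## Reference parameter set

The package ships one reference parameter set (the default
`ModelParameters`), used both as documentation of realistic magnitudes and
as the ground truth of the synthetic study.  It was chosen once to echo the
system's phenomenology: strong-site K_D = 30 µM; auxiliary sites with
microscopic K_D ≈ 8.8 mM whose cooperativity (a = 60) places the apparent
weak-phase midpoint near 410 µM (> 280 µM) with a Hill slope ≈ 5; transfer
at 3.0×10³ s⁻¹ at 75 mM NaCl, strongly salt-decreasing; per-site catalysis
vmax = 1900 s⁻¹ giving ≈ 1.6×10³ bp·s⁻¹ unwinding at 2 mM ATP (hence an
ATP consumption floor ≈ 3.2×10³ s⁻¹); 2 mM adenosine suppressing the
auxiliary on-rate to 20 % of its base value.  With these values the model
reproduces the qualitative signatures of the system: a biphasic titration
isotherm that collapses to one phase when the auxiliary sites are blocked
or removed; ≈ 4 nucleotides bound per enzyme in saturating equilibrium
dialysis versus ≈ 2 in the low-concentration regime; salt slowing
unwinding at 350 µM ATP but barely at 100 µM; adenosine slowing unwinding
at high ATP; and an upward shift of the apparent K_M when the auxiliary
sites are disabled.

The transfer rate here (10³–10⁴ s⁻¹) is deliberately placed where it is
partially rate-limiting for the buffer pathway.  If it were orders of
magnitude faster than every competing rate, its salt dependence would have
no observable consequence and the corresponding coefficients would be
unidentifiable from any of the modelled experiments.

## Synthetic data

`synthetic.GroundTruth` fixes the parameter set plus per-modality noise;
every generator is a pure function of (truth, design, seed) and its
zero-noise output is exactly the forward model.  Defaults:

* **Isotherms** — 20 log-spaced concentrations from 1 to 550 µM; signal
  w_c·⟨c⟩ + w_w·⟨w⟩ normalized at the top concentration, reporter weights
  (1.0, 0.7); Gaussian noise 0.02 of the unit-normalized signal.
* **Equilibrium dialysis** — closed-system equilibrium (free ligand solved
  from `2[N]_f + n([N]_f)·[protein] = [N]_i`), 1 % noise on the free
  concentration; regimes 45 µM enzyme / 1 mM nucleotide and 17 µM / 200 µM.
* **Stopped-flow transients** — master-equation observable mapped through
  the concentration-linear baseline `α·[mD] + β`, 1 ms dead time recorded,
  noise 1 % of the trace span; 0–100 µM mixing series.
* **Observed-rate (k_obs) curves** — the closed-form two-exponential
  reduction of the relaxation (below) plus 5 % noise, at 250–550 µM where
  both phases carry amplitude and the reduction is well-posed.  Below
  ~200 µM the two relaxation modes of the reference model nearly merge and
  any biexponential summary is ill-defined.
* **Unwinding time courses** — plateau/exponential-decay traces with
  `t_lag = intercept + length/rate`, the rate taken from the model at the
  record's condition; lengths 24/38/52 bp; anisotropy noise 0.005.
* **Tweezers traces** — piecewise-constant velocity (500 bp/s) with
  scheduled pauses, mapped through the extensible worm-like chain at a
  10→15 pN ramp, sampled at 2500 Hz with 2 nm r.m.s. extension noise.

The reference dataset (`gen_dataset`) spans NaCl {75, 200, 300} mM and
adenosine {0, 0.75, 2} mM for isotherms, k_obs curves at 75 and 300 mM
NaCl, and unwinding rates over an ATP grid to 2 mM plus NaCl
{150, 200, 300} mM and adenosine {0.75, 2} mM conditions.  The adenosine
mid-dose exists because the 2 mM dose drives `kw_on` onto its zero clamp,
where the slope α is one-sided-unidentifiable; the second k_obs salt level
pins the NaCl laws kinetically.  These are choices of the synthetic study
design, stated here once.

What the generators do **not** emulate: photobleaching, inner-filter
effects, instrument oversampling correlation, bead/trap Brownian dynamics,
force-dependent enzyme kinetics, tether-formation artifacts, or baseline
drift.  Passing the closed-loop tests therefore demonstrates correctness
of the estimators under the model's own statistical assumptions (Gaussian
noise, exact forward model), not robustness to the systematic errors of
real instruments.

## Numerical methods

* **Master equation** — `scipy.integrate.solve_ivp` (BDF) with the exact
  constant Jacobian, rtol 1e-8 / atol 1e-10; probability conservation is
  asserted to 1e-8.  Stationary distributions come from the null space of
  the generator (least squares with a normalization row).
* **Two-exponential reduction** (`biexp_rates`) — the model's stopped-flow
  prediction.  The observable relaxes as a sum over all eigenmodes of the
  generator; a stopped-flow analysis summarizes it by two exponentials.
  The reduction computes the Laplace transform of the decay analytically
  and interpolates it by a [1/2] rational function at four positive
  abscissae spread around the mean relaxation rate; the two poles are the
  effective rates.  This is exact for genuinely biexponential spectra and,
  unlike picking the two largest-amplitude eigenmodes, is a smooth
  function of the parameters (mode identities switch discontinuously).
  Degenerate spectra fall back to the single equivalent rate.
* **Steady unwinding rate** — stationary distribution of the
  catalysis-augmented generator; the 30 s trace integration
  (`simulate_unwinding`, linear fit over the final 80 %) agrees with it to
  1e-3 relative and both are exposed, the stationary form being the one
  used inside optimization loops.
* **Multi-exponential global fit** — variable projection: amplitudes and
  the shared concentration-linear baseline are solved linearly at fixed
  rates, the rates optimized by Levenberg–Marquardt in log space.  Rate
  standard errors come from the full-model Jacobian.  Points before the
  dead time are masked, never extrapolated.  Phase counting fits both
  models and requires both an AICc improvement > 10 and a single-exponential
  residual that leaves the ±1 s.d. noise band while the signal is above
  the noise floor.
* **Lag + decay fit** — profile strategy: at fixed (t_lag, k_diss) the two
  signal levels are linear; t_lag is scanned on a grid (default 20
  candidates), k_diss solved by bounded scalar minimization, and the best
  candidate polished by Nelder–Mead over all four parameters (the SSE is
  only piecewise smooth in t_lag).
* **Fit standard errors** — wherever per-point measurement errors are
  stated (isotherm s.e.m., rate uncertainties, lag s.e.), they are treated
  as known variances: covariances are *not* rescaled by the reduced
  chi-square, and the lag-vs-length line uses fixed-weight GLS.  Otherwise
  the usual residual-variance estimate applies.
* **Chung–Kennedy filter** — forward/backward running means over windows
  of 25/50/100 samples combined per window by inverse local variance to
  the power 2 (floor 1e-12), the three window outputs averaged with equal
  weights.  Output length equals input length; truncated windows at the
  edges.
* **Worm-like chain** — extensible high-force interpolation
  `x/L = 1 − ½√(kT/(F·P)) + F/S` with P = 50 nm, rise 0.34 nm/bp,
  S = 1200 pN, kT = 4.114 pN·nm; the inversion is exact (linear in L).
  Samples below 0.1 pN are flagged and interpolated from neighbors.
* **Pause detection** — histogram of filtered contour values (2 bp bins);
  local maxima with > 50 samples seed candidate dwells (peak bin ± one
  neighbor); fragments separated by less than the minimal translocation
  time (1 ms) or less than the minimal contour change (5 bp) are merged;
  dwells shorter than 2 ms are discarded.  The pause-density interval is
  computed both as printed in the source analyses (`1.96·√(tp/tc)`) and as
  the dimensionally consistent Poisson count error (`1.96·√tp/tc`); the
  first is the reproduction default, the second the recommended one.

## Global fitting

The objective accumulates uncertainty-normalized squared residuals per
experiment block (isotherms, dialysis, k_obs curves, unwinding rates),
dividing each block by its record count so no modality dominates.
Predictions: model isotherms (with the record's stated reporter weights),
closed-system dialysis counts, `biexp_rates` for k_obs, and stationary
unwinding rates — all at the record's condition, with an optional Q10
temperature multiplier (identity by default; Q10 = 2.5 when enabled).

Optimization is multi-start bounded least squares (trust-region reflective)
in log-magnitude space, with the "decreasing" sign of the three condition
slopes fixed.  Starts are (i) data-informed candidates built from quick
per-modality fits — double-Hill constants, fast-curve slope/intercept for
the catalytic rates, slow-curve level for the auxiliary rates, saturating
unwinding rate for vmax, with a small grid over the weakly constrained
cooperativity and transfer magnitudes — followed by (ii) log-uniform
random starts, all deterministic under the seed; the winner is polished
with a quadrupled evaluation budget.  Datasets that do not vary adenosine
or NaCl drop the corresponding slopes (with a warning), leaving a reduced
parameter set.

Bootstrap robustness perturbs every record by its stated uncertainty,
refits from the point estimate (the standard warm start), and summarizes
each parameter's replicate histogram by its mean and standard deviation;
failed replicates are excluded and reported via the convergence fraction.

Auxiliary-site-count selection refits the full scheme for each candidate
count and compares a small-sample-corrected AIC.  The kinetic modalities
are essential here: normalized isotherms plus two dialysis points cannot
bound the count from above (a 5- or 6-site scheme reproduces the
equilibrium data of the 4-site truth within noise), whereas the buffer's
replenishment kinetics and unwinding flux discriminate cleanly, producing
the improve-then-worsen objective profile around the true count.

## Problem sizes

The shipped test suite and acceptance script run the study at desk scale:
one reference dataset of ≈ 130 records per seed; five seeds for the
parameter-recovery study (each with 7–8 optimization starts); 100
replicates for coverage and classification checks; 100 synthetic tweezers
traces (3 s at 2500 Hz) for the pause loop; 20 for the acceptance script;
bootstrap demonstrations at 2–6 replicates with the n = 100 default left
to full runs.

## Known limitations

* The condition-law intercepts κ and ε extrapolate to zero NaCl from data
  measured at 75–300 mM; their noise sensitivity exceeds that of any
  directly probed quantity, and at the stated noise levels their
  fitted values can miss the truth by more than 20 % on unlucky noise
  draws even at the objective's global minimum.
* The cooperativity factor a is constrained mainly by the weak-phase Hill
  slope, which saturates with a; near a ≈ 60 substantial relative changes
  in a move the observable curves by little more than the 2 % isotherm
  noise, so a is the sloppiest parameter of the scheme.
* The two-exponential summary of a 15-state relaxation is a projection;
  it is well-posed only where the two dominant time scales are separated
  (the shipped k_obs design respects this).
* Free-ligand depletion by the enzyme is modelled in dialysis but not in
  titrations, where the free and total ligand concentrations are
  identified (standard for µM-scale enzyme against hundreds of µM ligand).
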