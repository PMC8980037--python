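# recbcd-kinetics

Quantitative kinetics of ATP binding, inter-site transfer and DNA
unwinding by the RecBCD helicase.

RecBCD initiates double-strand-break repair in bacteria by unwinding DNA
at up to ~1600 bp·s⁻¹, consuming two ATP per base pair — i.e. at least
3200 ATP·s⁻¹ per enzyme. Besides its two catalytic ATPase sites (RecB and
RecD), the enzyme carries cooperative, lower-affinity auxiliary
ATP-binding sites (RecC) that act as an ATP buffer: nucleotides bound
there can transfer directly to an empty catalytic site, boosting the ATP
flux to the motors when solution ATP is scarce. This package implements
that model and the full analysis chain of a multi-modal kinetic study of
it, for researchers in enzyme kinetics and single-molecule biophysics.

## The model

The enzyme state is `(w, c)` — ATP bound at `w` of 4 auxiliary and `c` of
2 catalytic sites. Catalytic binding follows sequential macroscopic rates
`k_s⁺[T]`/`k_s⁻`; auxiliary binding is cooperative (`k_w⁺[T]` for the
first molecule, `a·k_w⁺[T]` thereafter, unbinding `k_w⁻`); a bound
auxiliary ATP transfers to an empty catalytic site at `k_tr⁺` (reverse
`k_tr⁻`); each occupied catalytic site hydrolyzes at `v_max`, advancing
the duplex by 0.5 bp per ATP. Adenosine (which blocks the auxiliary
sites) and NaCl enter through nonnegative linear rate laws
`k_w⁺ = α·[adenosine] + β`, `k_w⁻ = γ·[NaCl] + δ`, `k_tr⁺ = ε·[NaCl] + κ`,
giving an 11-parameter global model. At equilibrium the occupancy follows
the binding polynomial

    Ψ(T) = (1 + K_s T + K_s² T²)(1 + K_w T + a K_w² T² + a² K_w³ T³ + a³ K_w⁴ T⁴),
    ⟨n⟩ = ∂lnΨ/∂lnT,

and titration curves are summarized phenomenologically by a sum of two
Hill terms (strong phase `K_s, n_s`; weak phase `K_w, n_w`).

Analysis stages (one module each): equilibrium isotherms and
equilibrium-dialysis stoichiometry; stopped-flow transients
(shared-baseline multi-exponential global fits, dead-time masking, phase
counting, hyperbolic k_obs curves); steady-state ATPase (quadratic
Briggs–Haldane); real-time unwinding (lag + decay fits, rate from the
lag-vs-length line); optical-tweezers traces (worm-like-chain conversion,
Chung–Kennedy filtering, pause detection, segment velocities, pause
density); and a joint 11-parameter fit with bootstrap robustness and
auxiliary-site-count selection. A synthetic-data module generates every
modality from a known ground truth, so the whole pipeline is validated by
parameter recovery.

## Worked example

```python
import numpy as np
from recbcd_kinetics import (ExperimentalCondition, fit_double_hill,
    steady_unwinding_rate, atp_flux_lower_bound, extension_to_contour,
    chung_kennedy, detect_pauses)
from recbcd_kinetics.synthetic import GroundTruth, gen_isotherm, gen_tweezers_trace

truth = GroundTruth()                       # reference parameter set + noise model

iso = gen_isotherm(truth, seed=1)           # biphasic titration, 1-550 uM
fit = fit_double_hill(iso)
print(f"strong phase: K_s = {fit.Ks:.1f} uM (n_s = {fit.ns:.2f})")
print(f"weak phase:   K_w = {fit.Kw:.0f} uM (n_w = {fit.nw:.2f}), partition p = {fit.p:.2f}")

rate = steady_unwinding_rate(truth.params, ExperimentalCondition(ligand_conc=2000.0))
print(f"unwinding at 2 mM ATP: {rate:.0f} bp/s  -> >= {atp_flux_lower_bound(rate):.0f} ATP/s hydrolyzed")

trace, schedule = gen_tweezers_trace(truth, duration_s=3.0, seed=4)
contour = extension_to_contour(trace)       # extensible WLC inversion, bp
contour.contour = chung_kennedy(contour.contour)
for p in detect_pauses(contour):
    print(f"pause: {p.start:.3f}-{p.end:.3f} s at {p.position:.0f} bp")
```

prints

```
strong phase: K_s = 34.9 uM (n_s = 1.19)
weak phase:   K_w = 341 uM (n_w = 5.46), partition p = 0.55
unwinding at 2 mM ATP: 1617 bp/s  -> >= 3233 ATP/s hydrolyzed
pause: 0.889-1.298 s at 950 bp
pause: 1.944-2.350 s at 1275 bp
```

The two dissociation constants separate the catalytic (tens of µM) from
the cooperative auxiliary phase (hundreds of µM, steep Hill slope); the
saturating unwinding rate implies the ATP-consumption floor; and the two
detected pauses match the dwells scheduled by the generator (0.9–1.3 s at
950 bp, 1.9–2.3 s at 1275 bp).

The same stages are scriptable through the `recbcdkin` command
(`generate`, `fit-isotherm`, `fit-transient`, `fit-atpase`,
`fit-unwinding`, `analyze-trace`, `global-fit`, `bootstrap`,
`select-sites`); every run writes JSON results plus a log with the
command, seed and config hash.

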