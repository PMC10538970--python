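# Methods

## Physical model and assumptions

The package treats unimolecular photoreactions in a slab-shaped,
continuously stirred reactor under a collimated monochromatic beam. A
mechanism is a directed graph of species interconverted by photosteps; all
stoichiometry is 1:1, so the total reactive concentration is conserved
exactly. Every parameter (ε, Φ, P0) refers to one irradiation wavelength; a
mechanism instance is always "at one λ_irr". Thermal (dark) steps,
bimolecular kinetics and polychromatic sources are out of scope.

The rate law couples every absorbing species through the total absorbance:
the light absorbed by species j is `Pa_j = ε_j l C_j · P0 · PKF(A_tot)`
with the photokinetic factor `PKF(a) = (1 − 10^−a)/a`, evaluated through
`expm1` for numerical stability and by its series limit `ln 10` at a = 0.
Inert spectators contribute a constant absorbance to `A_tot` (they compete
for photons but never react); no linearity-range condition applies to them
because only their constant absorbance enters the formalism. Concentrations
of the reactive species, by contrast, are assumed to lie in the
Beer–Lambert linearity range of their calibration graphs; the simulator
warns when `A_tot` exceeds 0.5, the usual practical guideline.

## Integration

Traces are produced by classic fixed-step fourth-order Runge–Kutta,
default dt = 0.1 s (dt ≤ 5 s accepted). A fixed step keeps runs
bit-reproducible, which the seeded fitting pipeline and the tests rely on;
the method's fourth-order convergence makes dt = 0.1 s accurate to ~1e-12
relative on the reference system (halving dt moves no concentration by
more than 1e-8 relative). Round-off negatives in [−1e-12, 0) M are clamped
to zero; anything more negative aborts with a suggestion to reduce dt.
Intermediate RK stages may transiently produce a negative total absorbance,
which is clamped to zero inside the rate evaluation only.

Steady states are detected when max |rate| < 1e-15 M/s. The default search
horizon is ~100 estimated half-lives: typical initial rates (~4e-7 M/s)
need 20–30 half-lives to decay below that threshold, so a much shorter
horizon would fail spuriously. Both threshold and horizon are arguments.
The two-species photoreversible case uses the closed form
`C_Y∞/C_X∞ = Φ_f ε_X / (Φ_r ε_Y)` instead. The half-life is defined
operationally as the first time the reactant crosses `(C_X0 + C_X∞)/2`,
linearly interpolated on the grid.

## Trace fitting (Φ-order protocol)

Each species trace is modelled as
`C_j(t) = C_∞,j + Σ_i ω_ij Log10(1 + cc e^{−k_ij t})` with a single `cc`
per mechanism. The protocol:

1. **Reactant first.** Number of terms starts at the number of steps
   touching the reactant and escalates (up to the mechanism's step count
   nΦ) until r² ≥ 0.999 and RMSE ≤ 6.33e-5 × the trace scale (the
   reference quality: 1e-9 M on a 1.58e-5 M trace). Nonlinear parameters
   (`cc`, the k's) are optimised by seeded multi-start
   Levenberg–Marquardt (32 starts, k inits log-uniform in [1e-4, 1e1] s⁻¹,
   cc inits log-uniform in [1e-6, 1e2]); the amplitudes ω are *projected
   out* by exact linear least squares at every step (variable projection),
   which removes most of the nonconvexity.
2. **Downstream species** are visited in order of graph distance from the
   reactant. They reuse `cc` and every upstream k exactly (so only their
   amplitudes are solved, linearly), adding genuinely new rate constants
   only when the quality bar is not met and the term cap allows.
3. **Joint polish.** The shared (cc, k) set is then re-optimised against
   all traces simultaneously (amplitudes still projected out), restarted
   from seeded random inits when any trace misses the bar. This keeps the
   k-sharing exact while escaping local minima the strictly sequential
   pass can fall into.
4. **Pruning** removes terms whose contribution to a trace is numerically
   zero, provided the quality bar survives.

Two hard constraints are imposed by parameter elimination, not penalties:
the model value at t = 0 equals the known initial concentration
(`C_∞ = C(0) − Log10(1+cc) Σω`), and `cc > −1` / `k > 0` via shifted-log
and log parameterizations.

The fit uses a grid of at most ~400 points taken half uniformly and half
geometrically (denser at early times): the t = 0 derivative of the fitted
model carries the initial-rate metric, and uniform sampling was measured
to bias it by up to ~1% on fast systems, early-dense sampling by ~5× less.

The total-absorbance trace follows the same template with its own coupling
factor `cc_A` (observed to differ from the species' shared `cc`, and
treated as independent) and its own amplitudes; its rate constants are
reused from the species fits. A constant series (isosbestic irradiation)
yields a zero-term model.

**Identifiability.** The individual (ω, cc, k) are not determined — many
parameter sets fit a trace equally well. The package promises only the
invariants: initial rates (identical across minima to ~0.1%), the shared k
set, and C_∞. For the primary photoprocess with a transparent product the
true solution can be singled out by pinning `cc = 10^{A_X0} − 1`, whereupon
the fitted k equals `Φ ε_X P0 l ln10`.

## Initial-rate metrics

`r0` per species is computed three ways: the closed-form rate law at t = 0
("theo"), the fitted models' analytic derivative at t = 0 ("fit"), and the
rate law evaluated at the simulated initial state ("rk"). The first and
third coincide mathematically (both are the generalized rate law at t = 0,
which also covers spectators and pre-seeded products); the fit route is the
independent check. Across randomized mechanisms whose fits meet the quality
bar the three agree within 1%; the regression of theo against fit over a
20-system battery has slope 1 within 0.01. Sweeps report the spectator
effect (percent reduction of r0X, matching the closed form
`100(1 − [A_X0/(A_X0+A_SPM)]·[1−10^{−A_X0−A_SPM}]/[1−10^{−A_X0}])`), the
CX0 effect (|r0X| saturating toward `Φ_sum P0`, fitted k's decreasing) and
the P0 proportionality. The wavelength-invariance ratio test compares
`r0X(λ1)/r0X(λ2)` with `[P0(λ1)(1−10^{−A_X0(λ1)})]/[P0(λ2)(1−10^{−A_X0(λ2)})]`
at t = 0 only, with a user-set tolerance (no error model is attached).

## Actinometry

`P0 = [E_sp λ/(N_A h c)]·S_irr/V_irr` converts a lamp spectral irradiance
to einstein s⁻¹ dm⁻³; constants are hard-coded at the conventional
precision (h = 6.62608e-34 J s, c = 299792458 m/s, N_A = 6.02214e23) so
worked values match the printed ones. The per-nm dimension is dropped for a
monochromatic beam, and the IUPAC q_n,p/V convention (which omits S_irr) is
reported alongside. Kinactinometry inverts the initial-rate law,
`P0 = −r0X/[Φ_sum(1 − 10^{−A_X0})]`, recovering simulated fluxes to <0.5%
across a 4-point grid. Actinometer calibration regresses each shared k and
each r0 against P0 by ordinary least squares *with* an intercept — a
nonzero intercept is a visible diagnostic, not absorbed silently.

## Intrinsic-parameter recovery

Given the topology, a trace per species, the total-absorbance trace and the
extrinsics, the solver: (1) runs the coupled fit; (2) selects timepoints by
greedy volume maximization plus swap refinement of the concentration
matrix's condition number (rejecting cond > 1e6; ties broken toward earlier
times, where rates are larger) and solves
`A_tot(t_m) = Σ_j ε_j l C_j(t_m)` for the ε; (3) forms rate-law equations
from the fitted models' rates and the absorbed fluxes computed with the
recovered ε (and the *measured* A_tot inside PKF), selects nΦ rows by the
same condition-driven greedy search — preferring unused species and larger
|rate|, skipping near-photostationary rows — and solves for all Φ. Each
timepoint contributes at most nsp−1 independent rate rows (they sum to
zero), which is why the procedure needs nΦ ≥ nsp−1; that precondition is
checked and warned about. Concentrations/rates come from the fitted models
by default (matching the reference procedure); `use_trace=True` switches
both stages to raw trace values with second-order finite-difference rates,
and the two routes agree within the fitting error.

Integrated quantum-yield formulas: for the primary photoprocess with a
transparent product the closed form
`Φ = (C_X0 − C_X(t)) / {(P0/k_X)[A_X0 ln10 − ln(1 + (10^{A_X0}−1)e^{−k_X t})]}`
is evaluated (k_X from the cc-pinned fit) and cross-checked against the
rearranged integrated rate law
`Φ = −ln[(10^{A_X(t)}−1)/(10^{A_X0}−1)]/(ε_X P0 l ln10 t)` to 1e-6; the
derivation chain fixes the sign (the conversion is divided by the absorbed
light, giving a positive yield). For general mechanisms the balance of the
step's source species is integrated by composite trapezoid on the trace
grid and solved for the one unknown Φ. Dividing the conversion by the
*total* absorbed light — the historical definition — is provided only to
demonstrate its inconsistency whenever any other species absorbs.

## Synthetic conditions

The generator reproduces the reference study conditions: CX0 = 1.58e-5 M,
P0 = 1.25e-5 einstein s⁻¹ dm⁻³, l = 1.65 cm, quantum yields of a few
percent, ε of order 1e4 M⁻¹cm⁻¹. Randomized sub-mechanisms of the
8-species/14-step template draw Φ uniformly from [0.01, 0.5] and ε from
[1e3, 5e4] M⁻¹cm⁻¹, and set CX0 for an initial absorbance of ~0.313 —
capped so A_tot can never exceed 0.6, the window in which the Φ-order
description of traces is established. Simulated traces are noise-free:
passing tests demonstrate the internal consistency and exactness of the
procedures on ideal data, not robustness to measurement noise, baseline
drift or calibration error, none of which are modelled.

## Problem sizes

The reference pipeline uses t_end = 300 s at dt = 0.1 s (3001 points);
battery traces are integrated until rates fall to 1e-3 of their initial
scale; fits operate on ≤ ~400-point grids with 32 multi-starts. These
choices reproduce the reference values to ≤0.03% and keep the full test
suite and the acceptance script in the minutes range.

## Known limitations

- **Purely irreversible consecutive chains** (e.g. X→Y1→Y2 with no reverse
  steps) are fitted by the Φ-order template only to ~1e-4 relative RMSE
  (r² ≈ 0.9999): the term cap i_j ≤ nΦ leaves too little freedom for these
  topologies. Intrinsics recovered through the fitted models are then good
  to ~1–2%; the raw-trace route recovers them to ~1e-4%. Reversible-rich
  mechanisms fit to 1e-9-scale RMSE and recover intrinsics to ≤0.05%.
- **Purely divergent branches** (Y1←X→Y3, no reverse steps) make the
  stage-2 system exactly singular — the product profiles are proportional,
  so only a combination of their ε is observable from A_tot. The
  condition-number guard rejects this with a diagnostic; branch quantum
  yields remain recoverable from initial rates.
- Outside the A_tot ≲ 0.6 window the Φ-order description degrades and
  initial-rate invariance with it; the simulator still integrates such
  systems faithfully but the fitting quality bars will flag them.
- No uncertainty propagation on recovered parameters (point estimates
  only), no model/topology selection, no multi-wavelength joint fitting.
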