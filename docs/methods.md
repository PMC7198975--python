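# Methods

## The model

`pilsync` implements a single-compartment delay-differential model of the
crosstalk between brassinosteroid (BR) and auxin signaling in the
*Arabidopsis* root, coupled through PILS (PIN-LIKES) intracellular
auxin-transport facilitators. Ten species evolve in μM over hours:

* **BR branch** — BR production is repressed by the delayed BZR homodimer
  (BZR^D at t − τ), closing a delayed negative feedback: BR activates
  (de-phosphorylates) its signaling by removing BIN2, BIN2 represses BZR,
  and BZR monomers dimerize reversibly into BZR^D.
* **Auxin branch** — nuclear auxin is produced at a constant rate and
  cleared in proportion to PILS abundance (`T·PILS`). Aux/IAA repressors
  are transcribed by the delayed ARF homodimer (ARF^D at t − τ) and
  degraded in an auxin-dependent manner; they sequester ARF monomers
  (`θ·AUXIAA·ARF`), which otherwise dimerize into ARF^D — a second
  delayed negative feedback.
* **Crosstalk** — BZR and ARF monomers also form a heterodimer
  (BZRARF^D), and PILS integrates both branches: its transcription is
  activated by ARF^D and repressed by BZR^D inside one saturating promoter
  term, `α_pAF·k_AF·ARF^D_τ / (1 + k_AF·ARF^D_τ + k_BZ·BZR^D_τ)`, and its
  protein is degraded BR-dependently (`δ_PBR·BR`).

One shared delay τ = 10 h stands for the transcription/translation/
signal-relay lag of the dimer-mediated feedbacks. BL treatment is a
constant external BR source φ = 0.05 μM/h added to the BR equation.
The ARF equation uses basal production minus first-order losses
(`α_ARF − ARF·(δ_ARF + θ·AUXIAA)`), mirroring the BZR equation.

Dimerization bookkeeping follows the equations as written: each
association event consumes one monomer, so the quantities conserved by the
dimerization fluxes alone are `BZR + BZR^D + BZRARF^D` and
`ARF + ARF^D + BZRARF^D` (property-tested).

All 33 rate/affinity/delay constants default to the experimentally
calibrated wild-type reference set (see `ParameterSet`); genotypes and
treatments are parameter substitutions (`bri1-6`: δ_brb 0.7 → 0.55;
`bzr1-d`: δ_bzb 0.5 → 0.3; `pils` triple mutant: α_pAF 1000 → 10;
PILS overexpression: α_bP 0.001 → 100 μM/h on top of the regulated
transcription; BL: φ 0 → 0.05).

### BIN-on-ARF variant

The variant in which BIN2 promotes ARF activity is implemented as
`θ_eff = θ · BIN2_ref / max(BIN2, ε)` with ε = 10⁻⁶ μM. `BIN2_ref`
defaults to the compiled parameter set's own fixed-point BIN2 level
(12.05 μM at reference), so `θ_eff = θ` at the operating point and the
modulation is a dimensionless factor of order one. Referencing the
BR-free level α_bin/δ_bin = 1000 μM instead would scale θ by 20–500×
throughout the oscillation (BIN2 ranges over ~2–47 μM), extinguish the
auxin branch and make the system needlessly stiff; both `bin2_ref` and
`bin2_eps` are configurable fields.

## Numerical integration

No maintained constant-lag DDE solver ships with the scientific stack this
package targets, so the integrator is built in: an adaptive, numba-compiled
Dormand–Prince 5(4) pair using the method of steps. The solver

* caps steps at τ and lands exactly on the discontinuity mesh t = k·τ,
  so every lagged evaluation falls in already-completed, smooth territory;
* evaluates y(t − τ) from its own accepted steps' quartic dense-output
  polynomials (4th-order interpolation, above the required 3rd);
* controls error with the standard mixed tolerance
  `atol + rtol·max(|y|)`, defaults rtol = 1e−8, atol = 1e−10, chosen so the
  scalar verification problem below is solved far inside its 1e−6 bound;
* is bit-reproducible for fixed inputs (no randomness, fixed initial step
  0.01 h).

Verification: on y′(t) = −y(t − 1), y ≡ 1 for t ≤ 0, whose method-of-steps
solution is an explicit piecewise polynomial, the maximum error over
[0, 4] is ~8e−16 (the solution has degree ≤ 4 there, which the 5th-order
pair reproduces exactly up to roundoff); over [0, 10], where truncation
error is real, errors decrease monotonically as tolerances tighten.

The history is a constant state for t ≤ 0. The initial state of the real
tissue is not experimentally constrained; the package default is the rest
state (all zeros), with the production terms driving the system into its
limit cycle.
Every trajectory records the history used.

Reporters are passive auxiliary states co-integrated with the core (one
extra equation each), so a single run yields the core plus all observables
consistently; passivity is asserted by comparing core trajectories with
and without reporters.

## Readout statistic for ratio predictions

Predicted treatment/genotype ratios are evaluated by default at the fixed
point of the lag-collapsed system (computed by relaxing the τ → 0 ODE with
LSODA and polishing with a hybrid Newton solve; residual < 1e−9). Rationale:
the calibration measurements are population/tissue-level fluorescence
readouts after short (3.5–12 h) treatments, far below the model's ~37 h
oscillation period — a quasi-steady operating-point comparison, not a
phase comparison. Time-averaging a 50 h window of an oscillating trajectory
instead measures the treatment-induced phase shift and produces ratios as
large as 20 for a reporter whose level barely changes; that statistic is
retained as an explicit option (`statistic="window_mean"`) but is not the
default. At the fixed point the model reproduces all four qualitative
response directions under BL: both PILS reporters fall (0.961, 0.952),
DR5 rises (1.058), DII falls (0.918) — numbers as computed by
`scripts/acceptance.py`.

## Synchrony measure

Peaks of the two signaling outputs (ARF^D, BZR^D) are detected after a
transient cutoff with a prominence filter (default: 1% of the
post-cutoff signal range, so near-flat traces report "no oscillation"
rather than ripple) and refined by quadratic interpolation through the
three samples around each maximum. Each peak of one series is paired
greedily, in time order, with the nearest unused peak of the other
(an `ordered` i-th-to-i-th mode is also provided). The synchrony score is
the sample standard deviation of the paired time differences: any constant
offset (phase locking) scores 0; drifting phases score high.

Because the model's variants lock at very different speeds, the analysis
window is part of the protocol and two are defined:

* **ONSET** (300 h from a uniform 1 μM history, cutoff 50 h) — captures
  the locking process itself. Used for the coupling comparison: with the
  BR → PILS coupling removed (k_BZ = 0, δ_PBR = 0) the auxin branch
  responds on the slow 1/δ_bx = 100 h timescale and the outputs drift
  (dispersion ~84 h) while the full model locks within the window
  (~0.15 h). A rest-state (zero) history is not usable here: without the
  coupling the ARF^D oscillation has not even emerged by 300 h.
* **SUSTAINED** (900 h, cutoff 300 h) — compares the synchrony genotypes
  *maintain* once settled; used for the PILS-dosage ordering
  (overexpression ≤ wild type ≤ *pils*) and the BIN-on-ARF variant, whose
  strongly altered PILS levels make the first 300 h pure transient.

A caveat the package makes explicit rather than hides: at steady state the
feedback-less model's ARF^D becomes a small-amplitude oscillation slaved to
BZR forcing through the residual heterodimer coupling, and is then
trivially phase-locked. The coupling comparison is therefore inherently a
statement about the transient/locking window, not about the asymptotic
regime.

The robustness scan perturbs all 32 non-zero kinetic constants
independently and uniformly within ±25% of reference (seeded), rescores
the coupled model under ONSET, and reports the fraction of draws that
retain ≥3 post-cutoff peaks and keep the coupled dispersion below the
unperturbed uncoupled reference. Failed draws are recorded, never fatal.

## Parameter estimation

The objective is the plain mean squared error between model-predicted and
observed mean ratios, minimized by exhaustive grid search (lexicographic
order, first-encountered tie-breaking) followed by seeded Monte-Carlo
refinement (uniform proposals around the incumbent, width a fraction of
each bound span, move on improvement). All stochastic operations require
an explicit seed.

Free parameters may be scoped to a genotype (`"bri1_6:delta_brb"`), in
which case the value replaces that genotype's compiled parameter only —
this is how mutant-specific constants are estimated while wild type keeps
its reference value.

Shipped presets reproduce the calibrated values: δ_brb (bri1-6) and δ_bzb
(bzr1-d) from mutant/wild-type PILS-transcription ratios; α_pAF (*pils*)
and δ_PBR from auxin-reporter (DR5/DII) comparisons between PILS-dosage
genotypes and wild type. Two identifiability facts shaped the presets:

* δ_PBR cancels out of any quasi-equilibrated protein ratio in which
  BR-dependent degradation dominates (ratio ≈ BR_ctl/BR_BL independent of
  δ_PBR), so BL/control ratios carry almost no information about it. The
  overexpression line breaks the cancellation: its DII reporter sits in
  the auxin-insensitive regime while wild type's does not, making the
  OE-vs-wild-type DII/DR5 comparisons strongly δ_PBR-sensitive.
* With a plain (unweighted) MSE, an observable whose ratio is numerically
  tiny contributes nothing. Cross-genotype comparisons are therefore
  recorded in the fold-change-above-one orientation (DR5 pils/wt, DII
  wt/pils, DII oe/wt, DR5 wt/oe), which balances the observables'
  weights without introducing a weighting scheme absent from the method.

## Synthetic data

The generator emulates the statistical shell of the calibration data:
triplicate ratio measurements of the four observables across a panel of
genotype/treatment comparisons, with multiplicative log-normal noise
(ratios of strictly positive fluorescence signals; replicate_i =
ratio·exp(ε_i), ε_i ~ N(0, σ²), default σ = 0.05; an additive-Gaussian
mode exists for robustness checks). It does **not** emulate imaging noise,
fluorophore maturation, cell-to-cell variability, or any systematic bias
between reporter and endogenous protein — so passing recovery tests shows
the estimation machinery is correct and the observables are informative
under the stated noise model, not that the reference parameter values are
uniquely determined by real images. The replicate noise level of real
measurements is unknown; σ is a free knob.

## Numerical and design details

* Output grids are `linspace(0, t_end, round(t_end/dt)+1)`, so the horizon
  is hit exactly; 300 h at 0.1 h gives 3001 samples.
* CSV floats are written with 17 significant digits; reloading reproduces
  values bit-for-bit. Every CLI run writes a provenance JSON (config,
  seeds, version).
* Fixed-point search: relax to t = 3000 h (20000 h fallback), polish with
  `scipy.optimize.root(method="hybr")`, accept residual < 1e−9 and
  states ≥ −1e−9.
* Peak-time refinement assumes a locally quadratic maximum; on the 0.1 h
  output grid this recovers sinusoid peak times to < 0.05 h.
* Degenerate inputs: ratio denominators below 1e−12 raise a
  degenerate-signal error; integration failures carry the failure time;
  scan draws that fail are logged and skipped.

## Known limitations

* Single compartment, deterministic kinetics; "noise" enters only as
  parameter perturbation and observation noise.
* One shared delay for all three delayed feedbacks.
* The synchrony score depends on the analysis window (see above); there is
  no window in which all comparisons are simultaneously *and* maximally
  discriminative, because the uncoupled variant locks asymptotically.
* δ_PBR is only weakly identified outside the PILS-dosage comparisons; its
  reference value should be read as order-of-magnitude.
* The fixed point used for ratio readouts is unstable at reference
  parameters (it is the focus inside the limit cycle); it is a modeling
  choice for quasi-steady readouts, not a claim about long-run dynamics.
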