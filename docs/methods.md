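# Methods

This note documents the models implemented in sterolflux, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## WHAM potential-of-mean-force reconstruction

Umbrella windows carry reaction-coordinate samples under a harmonic bias
w_i(x) = ½k_i(x − c_i)².  Samples are pooled into a common histogram
(default 200 bins over the pooled sample range, matching the common
gmx-wham default; configurable) and the unbiased per-bin probability p_b
and per-window free-energy constants f_i are iterated to self-consistency:

    p_b ∝ C_b / Σ_i N_i exp(β f_i) exp(−β w_i(x_b)),
    f_i = −kT ln Σ_b p_b exp(−β w_i(x_b)).

* **Convergence**: maximum change in the f_i below 1e-6 kJ·mol⁻¹ (default),
  capped at 100 000 iterations; non-convergence raises an error carrying the
  last residual.  The bias Boltzmann factors are evaluated at bin centers.
* **Anchoring**: the PMF is shifted so its minimum over an anchor interval
  is zero.  The default anchor is the last 10 % of the coordinate range,
  read as the unbound plateau; any interval can be supplied.  Profiles are
  therefore defined up to an additive constant, and all profile comparisons
  in the package (convergence metric, subsampling checks) remove the mean
  offset over the compared bins before measuring deviations.
* **Empty bins**: interior bins with no samples are flagged (NaN), never
  interpolated; every downstream operation skips flagged bins.
* **Temperature** is a required per-window field — coarse-grained profile
  data (323 K) and atomistic trajectory data (310 K) run at different
  temperatures, so no global constant exists.  Mixed-temperature window
  sets are rejected.
* **Equilibration**: each window has a time cutoff before which samples are
  discarded (the long-simulation workflows discard an initial transient;
  synthetic data default to 0).

**Errors — Bayesian bootstrap.**  The default scheme draws Dirichlet(1,…,1)
weights over complete windows, re-weights whole histograms, re-solves WHAM
(warm-started from the full-data constants) and anchors identically; the
per-bin standard deviation over rounds (default 2000) is the error field.
Re-weighting complete histograms matches the complete-histogram bootstrap
of gmx wham and is robust to intra-window autocorrelation; per-sample
multinomial resampling is available as an option.  The granularity of the
original workflow's bootstrap is not documented, which is why both schemes
are offered.

**Reading stationary points.**  Well depths and barrier heights read as
min/max over raw bins are biased by bin shot noise (a max over ~40 noisy
bins sits systematically above the smooth curve).  `PMFProfile.local_value`
fits a local quadratic over ±0.05 nm around the point of interest and
evaluates the fit, which is unbiased to leading order; barrier
measurements in the tests and the acceptance script use it.

**Convergence diagnostics.**  `convergence_series` refits the profile on
cumulative time prefixes; the reported metric is the offset-aligned
max |ΔPMF| between the last two prefixes over well-sampled shared bins
(bins holding at least 25 % of the median positive bin count).  Restricting
to well-sampled bins keeps pure shot noise in sparse edge bins from
dominating a metric that is meant to measure systematic drift.

## Alchemical estimators

The canonical input is the reduced-potential matrix u[k, n] (dimensionless,
u = U/kT) of every pooled sample evaluated at every λ state, plus the
per-state sample counts N_k.  Inputs in kJ·mol⁻¹ are reduced using the
supplied temperature at the I/O boundary.

* **MBAR** (primary): the self-consistent equations are solved by a short
  sweep followed by quasi-Newton minimisation of the equivalent convex
  objective Σₙ ln Σⱼ Nⱼ e^{fⱼ−u_jn} − Σⱼ Nⱼ fⱼ (analytic gradient),
  polished to a self-consistency residual below 1e-8.  Uncertainties are
  the standard asymptotic covariance computed via the thin SVD of the
  weight matrix.  The overlap matrix O_ij = Nⱼ Σₙ W_ni W_nj is attached;
  an adjacent-state overlap below 0.03 raises a warning.
* **BAR / exponential averaging** (cross-checks): Bennett's implicit
  equation is solved by bracketed root finding with numerically safe Fermi
  weights; the asymptotic Bennett variance is reported.  Vanishing Fermi
  means at the solution signal zero overlap and raise an explicit
  divergence error.  Exponential (Zwanzig) averaging carries a delta-method
  variance.
* **Decorrelation**: optional statistical-inefficiency subsampling
  (autocorrelation integrated to first zero crossing), off by default —
  the synthetic generators draw independent samples.  FEP file inputs
  default to discarding the first 4 % of each window as equilibration,
  configurable.
* **Cycles**: an absolute-binding total is site leg − reference leg −
  restraint bookkeeping terms; restraint contributions are accepted only
  as supplied values (an explicit gas-phase restraint-exchange leg), never
  computed analytically.  A relative perturbation ΔΔG is bound leg − free
  leg.  All cycle errors combine in quadrature.  Replicate results are
  reported as mean ± sample SD; forward/reverse perturbation pairs are
  checked for antisymmetry within combined error.

λ-schedule presets cover the two transformations the package models: a
29-window Lennard-Jones decoupling leg (step 0.05 to λ = 0.6, then 0.025
to 1 — the step sizes that actually yield 29 windows) and a 31-window
Na⁺→K⁺ exchange split into a mass phase (11 windows, step 0.1) and a
van-der-Waals phase (20 further windows, step 0.05, sharing the boundary
window).

## Transport-cycle assembly

Directed legs (site → site, ΔG ± e) chain from a start to an end site with
automatic reversal; the total is the signed sum and the error the
quadrature combination, legs being independent estimates.  A broken chain
or conflicting duplicate legs raise descriptive errors; duplicate legs with
identical estimates are interchangeable, and closed loops (start = end) are
supported.  Reporting rounds to integer kJ·mol⁻¹ half-up; raw floats are
preserved.  Legs marked non-physiological (an alternative ligand
orientation, a solvent-exposed egress path) are representable but never
composed unless explicitly allowed.  Cycle closure compares a direct
against an indirect estimate of the same ΔG: discrepancy with quadrature
error, a flag for whether zero lies in the combined 1σ interval, and a
flag for shared sign.

## Electrochemical coupling model

ΔG = RT ln(c_in/c_out) + zFΔV per mole of ion moved outside → inside, with
ΔV = V_in − V_out (resting potentials negative) and R = 8.314 J·mol⁻¹·K⁻¹,
F = 96 485 C·mol⁻¹, default T = 310 K.  Concentrations are treated as
activities.  The coupling direction is an explicit argument: an
influx-coupled cation (Na⁺: 12 mM in / 145 mM out) drives with −ΔG, an
efflux-coupled one (K⁺: 150 mM in / 4 mM out) with +ΔG.  Where the driving
energy is not positive the coupling is infeasible (e.g. K⁺ efflux beyond
its Nernst potential, ΔV_eq = −(RT/zF) ln(c_in/c_out) ≈ −97 mV at 310 K).
The stoichiometry is reported both as the continuous ratio
ΔG_export/ΔG_per-ion (as plotted against ΔV) and as its integer ceiling.

## Trajectory geometry

Coordinates are nm; boxes are orthorhombic (triclinic inputs are rejected)
and all distances use the minimum-image convention.  The probe cylinder
(default: 4 nm long, 1.3 nm radius, axis along the membrane normal,
center re-evaluated per frame when anchored to a Cα midpoint) uses closed
boundaries: a point exactly on the radius or cap is inside.  The
extracellular half is the positive axial side.  Water means the water
oxygen position; ions are single particles.  Contact criteria use all atoms
of a residue by default (side-chain-only is an option — whether the
original tabulation used heavy atoms only is not documented).  Trailing
"final N ns" summaries are a time-window parameter, never hard-coded.
Replicate trajectories aggregate as mean ± SD between repeats.  Density
grids are frame-averaged voxel counts, so the grid total equals the mean
selected-atom count per frame exactly; grids export as plain-text OpenDX.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* of the real inputs —
biased sampling under the documented umbrella parameters (k = 1000
kJ·mol⁻¹·nm⁻², 0.05 nm spacing, 323 K), λ-state sample matrices with exact
Boltzmann marginals, trajectories with countable planted features — with
analytic ground truth attached.  They do not emulate force-field physics,
solvent structure, sampling bottlenecks such as ligand reorientation, or
the slow orthogonal degrees of freedom that make real umbrella windows
require microsecond simulation.  Passing tests therefore demonstrate the
correctness of the estimators and probes, not the convergence of any
particular molecular system.

Monte-Carlo umbrella sampling uses a Gaussian proposal auto-tuned to ~40 %
acceptance during a discarded burn-in (2000 steps), then records every
5th step; a window whose acceptance leaves (0.05, 0.95) triggers a warning
with a suggested step size.  The λ-harmonic model interpolates stiffness
geometrically (always positive) so the reduced free energy of each state is
½ ln(k(λ)/k(0)) exactly; mean shifts leave it unchanged, which the tests
exploit as a zero-ΔG oracle with tunable overlap.  All generators are
deterministic under a fixed seed.

## Problem sizes used in the checks

The double-well recovery check runs 21 windows × 5000 samples (Metropolis,
thinned ×5), 200 bootstrap rounds, and 12 independently seeded replicate
datasets for the error comparison; the estimator checks use 10 000 exact
samples per λ state over 5 states.  At these sizes the barrier is
recovered to ~0.1–0.2 kJ·mol⁻¹ and the bootstrap error field sits within a
factor of two of the replicate spread (field medians over well-sampled
bins).  These sizes are the package's chosen study conditions for synthetic
validation; larger runs only tighten the statistics.

## Known limitations

* 1D, non-periodic reaction coordinates only; no 2D/periodic WHAM, no
  replica exchange, no nonequilibrium (Jarzynski) work analysis.
* The package consumes sampled time series and reduced potentials; it
  never evaluates force fields, soft-core potentials or restraint volumes.
* Chain composition resolves simple paths, not arbitrary leg graphs; no
  kinetic modeling.
* Single-ion coupling only: no simultaneous multi-species optimisation or
  proton-motive-force decomposition.
* Orthorhombic periodicity only; no rotational fitting in RMSD (intended
  for single-ion displacement, not flexible-domain superposition).
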