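# Methods

## Scope and data model

The package models the relationship between conceptual-DFT reactivity
descriptors of anthocyanin structural forms and DPPH radical scavenging
activity (% radical scavenged). Quantum chemistry is upstream: the unit
of input is a table of total molecular energies (heats of formation,
kcal/mol) for each compound and structural form, for the neutral
species and its electron-abstracted (N−1) and electron-added (N+1)
states, plus parent/phenoxyl energies where bond dissociation energies
are wanted. A parser for the `FINAL HEAT OF FORMATION` record of
MOPAC-style output text is provided as a convenience; the package never
invokes a quantum-chemistry program.

Compounds are described positionally: slots R1/R2 (ring positions
3'/5') take H, OH or OCH3; slots R3/R4 (positions 3/5) take OH or a
glycoside label. Positions 7 and 4' are treated as constitutively
hydroxylated, which is true of every compound in this class's reference
panel; glycosides (including acylated ones) are opaque labels, since
the analysis only needs OH-versus-sugar at each position. The
structural-form rule is generic — a quinoidal base exists iff its
deprotonation site carries a free hydroxyl — although in practice it
only ever removes QB5, for the four 5-glycosylated compounds.

## Descriptors

Finite-difference definitions in kcal/mol: I = E(N−1) − E(N),
A = E(N) − E(N+1), η = (I−A)/2, S = 1/(2η), χ = −μ = (I+A)/2,
ω = μ²/(2η), and BDE = E(A–O·) + E(H) − E(A–OH). Decisions:

- **No eV conversion.** Inputs and outputs stay in kcal/mol; the
  definitions are unit-consistent, and reference BDE tables for this
  class are printed in kcal/mol.
- **E(H) is data, not a constant.** The default 52.1 kcal/mol (the
  standard semi-empirical heat of formation of atomic hydrogen) is
  provided but overridable per record.
- **Adiabatic vs vertical is not distinguished.** The code subtracts
  whatever energies it is given; whether the ionized species were
  relaxed is a property of the upstream calculation.
- **η = 0 yields explicit `None`** for S and ω rather than ±inf, so a
  degenerate record cannot silently poison a correlation column; the
  screening stage reports such columns as failed instead of aborting.
- **BDE_min ties** break by ring-position order 3 < 5 < 7 < 3' < 4' < 5'.
  Published tables occasionally flag the other member of a tied pair;
  the packaged BDE fixture preserves the printed flags verbatim, and the
  tie-break applies only to recomputation.

## Descriptor screening

Pearson r per descriptor column with a two-sided p-value from
t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom (the textbook test,
and what standard statistics environments report). Star annotations at
p < 0.05 and p < 0.01. No multiple-testing correction is applied across
the descriptor × form grid — deliberately, to match common practice in
small-panel QSAR screening — and the report says so, so users can
adjust externally. Collinearity elimination is greedy on the
|r|-ranking with a pairwise R² threshold; at the default threshold of 1
it removes only exact duplicates and negations (χ vs μ, whose squared
correlation is identically 1 by construction). The default model
feature set {A_FC, χ_FC, I_QB7, nOH} is configuration, not hard-coded.

## The neuro-fuzzy model

First-order Takagi–Sugeno system built by grid partition: m triangular
membership functions per input (default 2), peaks at m equally spaced
points over the observed range, each triangle extending one grid step
beyond its peak so the family covers the range with positive total
membership; every combination of per-input functions is one rule
(2⁴ = 16 with the defaults), each with a linear consequent
c0 + Σ cj·xj. Inputs are min–max scaled to [0, 1] before partition by
default; the flag is recorded in the serialized model.

Training is hybrid: each epoch (1) solves all consequent coefficients
at once by linear least squares on the normalized-firing design matrix,
(2) records the training MSE at that optimum, then (3) moves each
membership vertex one analytic gradient step, re-clipping
left ≤ peak ≤ right. The final epoch ends on the consequent solve, so
the returned model is least-squares optimal for its premises and
consistent with the last trace entry. Rationale for hybrid as the
default: with 16 rules × 5 coefficients = 80 consequent parameters
against ~21 training rows, pure backpropagation is badly conditioned,
while repeated least squares on a fixed design is exactly
non-increasing in training error. The least-squares step is itself
underdetermined at that size; a ridge penalty (default 1e-6) or, at
ridge 0, the minimum-norm solution keeps it well defined. A pure
gradient mode (`consequent_solver="gradient"`) is retained for
comparison. Subgradients at the non-differentiable triangle vertices
are taken as 0 (measure-zero points); a learning rate of 0 freezes the
premises. Grid initialization is deterministic; the seed only affects
optional row shuffling.

Consequence of the overparameterization: on ~21 training rows the
model can interpolate the data almost exactly (training Q² ≈ 1), so
training-set metrics on real-size panels mostly reflect capacity, not
generalization — which is exactly why validation is bootstrap-based.

Models serialize to versioned JSON (nested keys for inputs, membership
functions, rules); the round trip is lossless to the bit, and
predictions from a reloaded model are identical.

## Validation

MAE and Q² = 1 − SSE/SST with SST about the mean of the observed
activities (training-set mean convention). Dispersion comes from a
pair-resampling bootstrap: the n (observation, prediction) pairs of the
already-fitted model are resampled with replacement `n_boot` times
(default 1000) and both metrics recomputed per replicate; the report
carries mean ± SD over replicates next to the point estimates. This
convention was chosen because the SD of the resampled MAE has the
closed form sqrt(Var_pop(|residual|)/n), which the tests verify, and
which reproduces the reference panel's printed ±0.35 / ±0.32 — a
retraining-per-replicate scheme would not. A retraining bootstrap is
nevertheless available (`bootstrap_retrain`) for comparing conventions.
Replicates whose resampled observations are constant have no defined
Q²; they are skipped for Q² only and counted in the report.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the chemistry: unit-scale jointly Gaussian descriptor columns with
a common pairwise correlation (default 0.45), and an activity equal to
their conditional-mean linear combination plus Gaussian residual,
rescaled to mean 27 / SD 7 to match the spread of the reference panel's
experimental activities. Target descriptor–activity correlations
(defaults: A_FC 0.67, χ_FC 0.70, I_QB7 0.67 — the magnitudes observed
for the reference panel — and nOH 0.55, a typical literature-scale
value not printed in the reference correlation table) are embedded in a
joint correlation matrix whose positive semi-definiteness is checked by
eigenvalue before sampling; infeasible target combinations are rejected
rather than silently clipped. The inter-descriptor correlation is not
decorative: the default targets are jointly infeasible under
independent features (Σr² ≈ 1.69 > 1). `noise_sd=None` (default) uses
the residual implied by the correlation structure, so realized sample
correlations match the targets; an explicit value (e.g. 0 for a
noiseless planted surface, used by the recovery tests) overrides it. An
optional mild x₁·x₂ interaction term (γ = 0.3) produces smooth
nonlinearity. Generation is bit-reproducible given spec + seed.

What the generator does **not** emulate: real quantum-chemical energy
scales (energies in end-to-end tests are free inventions consistent
with the descriptor definitions), non-Gaussian descriptor marginals,
measurement error structure in DPPH assays, and any chemistry linking
substituents to descriptor values. Passing tests on synthetic data
therefore demonstrate statistical correctness of the pipeline, not
chemical validity of a fitted model.

The packaged fixtures (compound registry, experimental/predicted
activities, per-position BDE table) are exact transcriptions of the
reference panel's printed tables, shipped as delimited text with a
SHA-256 manifest verified at load time.

## Problem sizes in the test suite

Tests run the study-scale configuration (21 compounds, 4 inputs, 16
rules, 100 epochs, 1000 bootstrap replicates) wherever a check refers
to it; statistical property tests use the smallest sizes at which the
property is sharp (n = 150–500 for correlation recovery and noise-floor
checks, 300 × 4 null replicates for the type-I-error rate, 20 000
replicates for the exhaustive-enumeration bootstrap comparison). The
whole suite completes in a few seconds.

## Known limitations

- Positions 7 and 4' are assumed hydroxylated; compounds glycosylated
  or methoxylated there would need the positional table extended (the
  form-availability rule itself is already generic).
- No pH speciation: the package treats forms as alternative descriptor
  sources, not as an equilibrium mixture.
- No applicability-domain analysis or y-scrambling; with n ≈ 21 the
  bootstrap dispersion is the only uncertainty estimate offered.
- Q² here is computed on training-set predictions; it is a fit
  statistic under resampling, not an external-test estimate.
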