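# Methods

## Problem setting

A single nanocomplex (AuNP-mTHPC) sensitises tumour cells to two laser
modalities: 650 nm activation produces reactive singlet oxygen (PDT), 532 nm
activation produces heat (PTT). Treatment outcome is summarised by the cell
death rate D ∈ [0, 1], a probability measured by flow cytometry ~24 h after
irradiation. The package models D as a function of the two controllable dose
parameters, laser duration τ (minutes) and intensity I₀ (mW/cm²), and builds
planning and combination analysis on top of that surface.

## Death-rate estimation from events

Each event carries forward scatter (size proxy), side scatter (granularity),
a pulse-area signal, and propidium-iodide fluorescence. PI only enters cells
with compromised membranes, so a high PI signal marks dead or badly damaged
cells.

1. **Gating.** Debris is removed by a forward-scatter floor (default 5000
   a.u. against the generator's live median of 50 000), doublets by the
   fsc_area/fsc ratio (default bound 1.5; singlets sit near 1, aggregates
   near 2). Gates label rather than drop events, so exclusion is auditable
   and idempotent.
2. **PI threshold.** Manual live/dead gating is replaced by a quantile rule:
   the threshold is the q-quantile of pooled control events. By
   construction ~(1 − q) of control events score dead. q must satisfy
   1 − q > control background death, otherwise the threshold climbs into the
   dead PI population and misses most dead cells on treated samples; with
   ~4% background the default is q = 0.95, leaving ~1% live false positives
   that control subtraction removes.
3. **Control subtraction.** The treatment-attributable rate is
   clip(raw − mean(controls), 0, 1), the controls being the laser-only and
   nanoparticle-only samples; the untreated control is kept for diagnostics.
   Negative differences clip to zero because a death rate is a probability.
4. **Replicates** are averaged at the condition level before surface
   fitting; per-replicate values are retained for spread reporting.

All rates are carried as fractions in [0, 1]; percentages appear only at
reporting boundaries (two decimals for rates, integers for percent gains).

## Dose–response surfaces

Three families fit D(τ, I₀) to condition-level points:

- **Locally weighted regression (2-D LOWESS).** τ and I₀ are standardized
  to unit variance; each prediction is a weighted linear fit over the span
  fraction (default 0.28, minimum 3 points) of nearest training points with
  tricube distance weights, times bisquare robustness weights computed in
  (default) 2 re-weighting passes on training residuals. The local degree,
  distance metric and robustness scheme are this package's choices; the
  method is specified at the property level (local, robust,
  span-controlled), not as a bit-for-bit port of any particular smoother.
- **Thin-plate spline.** Exact interpolation (smoothing 0) via radial basis
  functions; training values are reproduced to numerical precision, so
  training diagnostics are residual 0, R² = 1 by construction. Replicated
  locations are pre-averaged.
- **Degree-2 polynomial.** Ordinary least squares on the basis
  (I₀², I₀, τ², τ, τI₀, 1); exactly six coefficients, rank-checked.
  Reference coefficient sets for PDT (−0.001, 0.04, −0.014, 0.17, 0.002,
  −0.392) and PTT (−0.0003, 0.02, −0.0006, 0.018, 0.003, −0.14) are built
  in as the published models and as generator ground truth.

Raw model output is clipped to [0, 1] after evaluation (the polynomial's
negative constant term makes raw negatives possible at low doses).
Predictions outside the convex hull of training locations are flagged as
extrapolations. Diagnostics report signed residual mean and SD in
percentage points and R² = 1 − SS_res/SS_tot on fractions, against training
or held-out points alike; R² is undefined (reported missing) when the
observed values have zero variance.

A caveat that matters for testing: the reference polynomials are *not*
valid fractions everywhere on the training grid — the PDT surface is
negative at (τ = 1, I₀ ≤ 6) and the PTT surface slightly exceeds 1 at
(8, 30). Clipped values are no longer quadratic, so exact
coefficient-recovery checks use an interior design (τ ∈ {2.5, 4, 8},
I₀ ∈ {6, 15, 20, 25}) where both references lie strictly inside (0, 1).

## Three-state fate model

Two thresholds partition death rates into unaffected / affected / dead.
Boundary convention is fixed: dead is open at D_TH (d > D_TH), affected is
the closed interval [H_TH, D_TH]. Defaults D_TH = 0.6, H_TH = 0.3; the
unaffected band corresponds to death rates comparable to untreated
controls. Population probabilities are empirical state fractions and sum to
one exactly. State maps evaluate a fitted surface over a (τ, I₀) lattice
and export tidy (tau, intensity, death_fraction, state) tables.

## Combination model

Consecutive courses compose through first-course states:

    P(D) = P_d1·1 + P_a1·P(d2|a1) + P_na1·P(d2|na1),

dead cells staying dead. With no affected mass and no sensitisation this
reduces to the additive lower bound B_L = p₁ + (1 − p₁)p₂ — the kill rate
of two independent Bernoulli courses, which Monte-Carlo simulation confirms.
The gain S_G is (observed or composed) combined rate minus a baseline:
the bound in prediction mode, or the matched-total-duration single-modality
course in experimental mode. The gain decomposes into affected and
unaffected components, P_a1·Δp(d2|a1) + P_na1·Δp(d2|na1), whose sum equals
the direct difference of composed rates (the dead term cancels); this
algebraic identity is tested to 10⁻¹².

Classification: synergetic if S_G > ε, antagonistic if S_G < −ε, additive
otherwise. The default additive band ε = 0.01 (one percentage point)
follows the convention of reading sub-1-pp course gains as additive.
Integer percent gains are always explicit about both the denominator
(single-course rate or lower bound) and the reduction convention (truncate
toward zero or round); both conventions appear in published reporting and
neither is defaulted silently.

## Constrained planning

The planning loss is (D_desired − D(τ, I₀))², minimised subject to
τ ≤ τ_max, I₀ ≤ I₀_max. The solver enumerates a regular lattice (default
steps 0.1 min × 0.5 mW/cm²) — exact, deterministic and auditable — and
optionally refines continuously with bound-constrained L-BFGS-B seeded at
the lattice optimum, never returning a worse loss. Ties prefer smaller τ,
then smaller I₀, operationalising latency and safety preferences that the
scalar criterion drops. Constraints are treated as closed since the
training grid itself uses the boundary settings (8 min, 30 mW/cm²).

## Synthetic data generator

The generator emulates the study conditions: per modality, a training grid
of intensities {1, 6, 15, 30} mW/cm² × durations {1, 4, 8} min with 2
replicates; held-out test settings (τ, I₀) ∈ {(2, 25), (6, 12), (7, 18)};
combined-course settings {(4, 6), (4, 15), (8, 6), (8, 15)}; and untreated
/ laser-only / nanoparticle-only controls.

- **Truth.** Per-replicate death probability is clip(truth(τ, I₀) +
  N(0, σ), 0, 1) with the reference polynomial as default truth surface and
  σ = 0.03 — mid-range of the reported per-condition replicate SDs (about
  2–7 pp). Treated samples add the control background (default 4%, SD 2.5%
  across control samples) so control subtraction is exercised honestly.
- **Events.** Dead cells draw PI from a high log-normal component (median
  2000 a.u. vs 100 for live, σ_log = 0.5) and carry reduced forward scatter
  (factor 0.6, reflecting shrinkage of dead cells); debris has sub-floor
  fsc; doublets have fsc_area ≈ 2·fsc. Default injection: 5% debris, 3%
  doublets.
- **Ledger.** Every sample's true probabilities and every event's hidden
  label are returned; ledger counts reconcile with emitted events exactly.
  All randomness flows from one explicit seed; same seed, same bytes.

What the generator does **not** emulate: optical physics and heating
kinetics (the truth surface shape stands in for them), spectral overlap or
compensation, instrument drift, non-log-normal autofluorescence tails, and
any dependence of artifact rates on treatment. Passing tests therefore show
the estimation chain is correct under a faithful-but-idealised data model,
not that the defaults match any particular cytometer.

## Numerical conventions and degenerate inputs

- Death fractions validated to [0, 1] everywhere; composition output and
  subtraction results clipped.
- Thin-plate fits reject < 3 distinct locations; poly2 rejects
  rank-deficient designs with a named error; LOWESS enforces span·n ≥ 3.
- Gating that removes every event flags the table invalid for fitting
  rather than producing silent NaNs; empty populations and empty control
  lists raise.
- Lattice tie-breaks and exact-threshold classifications are deterministic;
  values landing exactly on a state threshold follow the documented closed/
  open convention (float summation order can flip labels for values within
  ~1e-16 of a threshold — maps built from vectorised evaluation are
  consistent within themselves).
- Surface JSON stores poly2 coefficients losslessly; lowess/thinplate
  surfaces are stored as training points + options and re-fitted
  deterministically on load.

## Limitations

- The conditional death probabilities P(d2|a1), P(d2|na1) are model inputs,
  not estimated from data; the package computes with them but cannot
  measure them from a single-course assay.
- Surface uncertainty (bootstrap bands) and higher-order polynomial
  families are out of scope, as are binary cytometry file formats (events
  are CSV), spectral compensation, and model-based gating.
- State thresholds are conventions, not values calibrated against long-term
  cell-tracking outcomes.
- The planner optimises kill rate only; normal-cell sparing and
  multi-objective trade-offs are not modelled beyond the lexicographic
  preference for shorter, gentler settings.
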