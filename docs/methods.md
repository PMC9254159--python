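# Methods

## The model

`msctrace` treats a 48 h tracer incubation as an isotopic and metabolic
steady state: fluxes are constant (per unit cell protein), intracellular
pools are turned over fast relative to the incubation, and the tracer has
fully replaced its medium nutrient from t = 0. Under these assumptions the
mass-isotopologue distribution (MID) of every pool is determined by flux
ratios alone, and label propagation reduces to linear balance equations on
the atom-mapped network. No kinetic (time-course) simulation is attempted;
the study design this package mirrors measures a single late time point.

### The reference network

The shipped network is the smallest atom-mapped model that reproduces the
isotopologue patterns the analysis interprets: lumped glycolysis
(G6P → F6P → 2 trioses → 3PG → PEP → pyruvate), the oxidative
pentose-phosphate branch (G6P → R5P, losing C1 as CO₂), lactate exchange,
PDH (losing pyruvate C1), citrate synthase (OAA + acetyl-CoA), the
oxidative TCA arc (citrate → AKG → succinate → malate → OAA, with CO₂
losses), reductive carboxylation (AKG + CO₂ → citrate), malic enzyme,
glutamine → glutamate, glutamate ↔ AKG, OAA ↔ aspartate, proline
synthesis, and uptake/secretion boundaries. Deliberate omissions: pyruvate
carboxylase (whether these cells carry anaplerotic pyruvate→OAA flux is
unknown; the network omits it and nothing downstream assumes it), fatty
acid synthesis (cytosolic citrate leaves as secretion), and compartment
separation (LC-MS of whole-cell extracts cannot distinguish cytosolic from
mitochondrial pools, so they are merged).

Conventions: carbon positions are 1-based biochemical numbering; CO₂ is an
infinite unlabeled pool (refixation of labeled CO₂ is ignored — the M+5
citrate signature of reductive carboxylation presumes unlabeled CO₂);
succinate (standing in for succinate + fumarate) is rotationally
symmetric, and every flux producing it is split 50/50 over the two carbon
orientations; reversible steps are written as two opposing irreversible
reactions, which keeps the balance equations linear.

### Simulators

The production solver decomposes the network into elementary metabolite
units (EMUs): carbon subsets whose labeling balances independently. EMUs
are collected backward from the requested metabolites; each size-k block
is a linear system A·X = B solved directly (with a damped fixed-point
fallback if the direct solve fails), with smaller-size solutions entering
through convolutions at condensation reactions. The testing oracle ignores
the EMU reduction entirely: it iterates the full positional-isotopomer
balance (2ⁿ states per metabolite) to a fixed point (tolerance 1e-12,
iteration cap 200 000) and marginalizes to MIDs. The two implementations
share only the network data structure; their agreement (< 1e-8 per MID
entry on every shipped network, including symmetric scrambling, cycling,
condensation and impure-tracer cases) is a regression-tested invariant.

Zero-production pools under a balanced flux assignment are pinned to
unlabeled rather than treated as errors: only zero-flux reactions consume
them, so their labeling is immaterial. A metabolite with no producing
reaction at all (a structural orphan) is still an error.

### Natural-abundance correction

Simulated MIDs are tracer-only. The measurement layer adds natural ¹³C
with the binomial forward model M[i,j] = C(n−j, i−j)·p^(i−j)·(1−p)^(n−i),
p = 0.0107 by default; correction inverts it by non-negative least
squares, which cannot produce negative fractions on noisy input, and
renormalizes. The correction is carbon-only: O/N/H/S isotopes, tracer
impurity, and resolution-dependent effects are out of scope. Peak-area
vectors whose total falls below a configurable floor are marked missing
instead of corrected, to avoid amplifying noise. A `--no-correction`
switch propagates raw fractions for sensitivity analysis; downstream
tables carry the MID state (`na_corrected` vs `raw`) explicitly.

### Exchange rates

Calibration is unweighted OLS with intercept on the five-point design
(0.25×, 0.5×, 1×, 2×, 4× of the nominal medium concentration) — the
simplest defensible model for the stated design. Quantification is inverse
prediction times well volume (μM × ml = nmol); negative predictions are
clipped to zero with a warning, since concentrations are physical. The
rate statistic divides the spent-minus-reference amount by the mean of
day-0 and day-2 protein **and by the incubation duration in days**
(default 2). The underlying protocol's printed formula has no explicit
time divisor while calling the result a per-day rate; this implementation
makes the units honest and exposes `duration_days=1` for the per-48 h
reading. The mean-protein denominator is itself a discrete approximation
of the exponential-biomass exposure ∫P(t)dt; for doubling times ≥ 48 h
over a 48 h window the two differ by < 8% (a tested bound), and the
approximation cancels exactly in protein-free ratios such as the
glucose→lactate percentage.

### Attribution statistics

All attribution quantities are direct functionals of corrected MIDs; no
inverse flux fitting is performed. The reductive/oxidative split of
citrate synthesis under a U-¹³C₅ AKG-precursor tracer uses M+5 as the
reductive proxy and M+4 as the oxidative proxy (one CO₂ lost, unlabeled
acetyl-CoA gained); second-turn TCA products smear into M+1..M+3 and are
reported separately as a multi-turn/ambiguous window rather than folded
into either proxy. The exogenous-pool fraction reads M+0 under a purity-1
tracer and refuses impure tracers, where M+0 is uninterpretable. Secreted
citrate is a two-component pool — pre-existing medium citrate (100 μM,
unlabeled) plus de-novo secreted citrate carrying the intracellular MID —
and its labeled fraction is reported against the total pool by default
(matching how such numbers are usually quoted), with a de-novo denominator
available that subtracts the pre-existing amount. The three-tracer citrate
source panel reports each arm's 2..5-labeled window side by side; the
windows come from separate experiments, so their sum is not forced to 1
and the unattributed remainder is reported explicitly.

### Statistics

The t tests delegate to scipy (two-tailed; zero-variance inputs are
flagged degenerate rather than given a p-value). Holm–Šídák is the exact
step-down rule with running-maximum monotonicity. The BKY two-stage FDR
follows the published adaptive procedure: stage 1 is a linear step-up at
q′ = q/(1+q), m̂₀ = m − r₁, stage 2 a linear step-up at q′·m/m̂₀ (no
stage-1 rejections ⇒ none overall; m̂₀ = 0 ⇒ reject all). Because the
two-stage rule does not define q-values uniquely, this package defines a
feature's q-value as the smallest nominal q at which the rule rejects it,
found by bisection — self-consistent with the rejection function by
construction, and one valid convention among several. Ties keep input
order under a stable sort. Both procedures are cross-checked against
statsmodels in the test suite. Volcano fold changes use group means of raw
(protein-normalized) intensities, the common volcano convention.

## The synthetic-data generator

The generator emulates the full study design: 8 donor lines × {21%, 1%}
O₂ × three tracer arms, 48 h in 0.8 ml wells (12-well plate, 3.8 cm²,
seeded at 10 000 cells/cm²), spent vs cell-free reference media, five-point
standards, day-0 protein from parallel wells, intracellular and
secreted-citrate isotopologue tables, and total-pool intensities for the
volcano analysis.

**Flux regimes.** The two shipped flux assignments encode the studied
phenotype: at 1% O₂ glycolytic uptake rises > 2-fold (3.20 vs 1.40
nmol·μg⁻¹·day⁻¹) at an unchanged 80% glucose→lactate conversion, the
oxidative PPP share rises, PDH is nearly silent (0.02 vs 0.45), citrate
synthesis shifts from citrate synthase to reductive carboxylation (M+5
share of M4+M5 ≈ 0.89 vs 0.04), glutamate uptake triples, and citrate
secretion stays positive (0.08 vs 0.10). Absolute magnitudes are
mid-range literature values for cultured stromal cells; both assignments
balance every internal metabolite to < 1e-9. Doubling times are 52 h
(21%) and 72 h (1%).

**Biology and noise.** Donor heterogeneity is a lognormal multiplier
(σ = 0.15) applied to *all* fluxes of a donor-condition — scaling preserves
the steady state and leaves MIDs unchanged, which is exactly what a
proportional metabolic-capacity difference does — plus per-donor doubling
times (σ = 0.08) and donor × metabolite pool-size effects (σ = 0.20,
shared across oxygen conditions so paired tests see real pairing).
Growth is exponential (no lag or contact inhibition). Measurement noise is
multiplicative lognormal, mean-one, placed where it physically enters:

- standards areas, intracellular isotopologue areas, protein: the
  scenario CV (default 8%; the recovery analyses use 5%);
- per-well exchanged amounts: the same CV (well-to-well variability of
  the flux realization);
- medium-sample areas (spent and reference): a small within-batch
  instrument repeatability (CV 0.3%).

The split matters. Medium pools are large relative to 48 h exchanges
(glucose: ~4450 nmol/well vs a ~60–120 nmol depletion), so noise applied
independently to raw spent and reference areas at several percent would
make the difference — and hence the rate — unrecoverable at any realistic
replication. In a real batch, spent media, reference media and standards
are interleaved injections quantified against the same curve: shared
response drift is absorbed by the calibration, additive offsets cancel in
the spent-minus-reference difference, and what remains is injection
repeatability. The generator encodes that structure rather than a single
undifferentiated area CV; consequently rate recovery is limited by
calibration error, biology and the mean-protein approximation, as it is in
practice.

**What passing recovery tests do and do not show.** The generator shares
the analysis pipeline's structural assumptions (steady state, the network
topology, carbon-only isotopes, exponential growth), so parameter-recovery
results demonstrate the estimators' correctness and noise behavior under
those assumptions — not robustness to model misspecification,
chromatographic artifacts, missing isotopologues, compartmentation, or
non-steady labeling, none of which are simulated.

## Numerical choices

- EMU linear solves: `numpy.linalg.solve`, damped Jacobi fallback
  (damping 0.5, tolerance 1e-14) for singular/ill-conditioned blocks.
- Brute-force fixed point: tolerance 1e-12, cap 200 000 iterations;
  convergence is linear with rate set by the cycling flux fraction.
- Steady-state tolerance: 1e-6 relative to the largest flux (numerical,
  not biological).
- NNLS correction renormalizes and reports the residual; all-zero area
  vectors are errors, sub-floor totals are missing values.
- Doubling-time fits treat slopes ≤ 1e-12 (log2/h) as no growth → ∞.
- BKY q-values: bisection to 1e-10 on the nominal q axis.
- Degenerate inputs (zero variance, single pairs, empty tables, unknown
  ids) raise typed errors naming the offending entity; they are never
  silently coerced.

## Known limitations

- The atom map of citrate/aconitase is a lumped convention: mass shifts
  are exact, but positional assignments within citrate are not
  stereochemically resolved (irrelevant for MID-level statistics, which is
  all this package computes).
- Natural-abundance correction ignores non-carbon isotopes and tracer
  impurity; for metabolites with large O/Si adduct contributions a
  formula-aware correction would be needed.
- The reductive (M+5) / oxidative (M+4) proxies undercount multi-turn
  contributions by design; the ambiguous window is reported, not resolved.
- Exchange rates assume no evaporation and protein-proportional activity;
  cell-count-based normalization is not implemented.
- The glutamate-arm labeling in the default scenarios is stronger than a
  small 98 μM medium pool would usually produce, because the merged
  glutamate pool turns over quickly in this network; cross-arm comparisons
  remain internally consistent since every arm shares one flux regime.
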