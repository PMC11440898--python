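# Methods

`shadea` assesses the performance of a community mental-health system at
the level of small health catchment areas (SHAs). Each SHA is described by
structural rates (service availability, workforce, beds, places per
100,000 adults) and utilisation rates (treated prevalence and
frequentation per 1,000 adults). The pipeline chains four models:

1. **Monte Carlo uncertainty engine.** Administrative registries provide a
   single cross-section, so each observed rate is widened into a sampling
   distribution and replicate datasets are drawn. The default family is
   triangular with the observed rate as mode and relative half-width
   `spread = 0.2` (support `[0.8r, 1.2r]`, floored at 0); a symmetric
   truncated normal on the same support and a point mass are also
   available. `spread` is configuration, not an estimate: no longitudinal
   data exist from which to fit it. Sampling proceeds in batches
   (default 100) up to a cap (default 500). After each batch the engine
   computes, per area *i*, the relative standard error of the mean RTE,
   `err_i = 100 · (SD_i/√R)/mean_i`, averages it over areas, and stops
   once the average falls below the threshold (default 2.5%). A per-area
   mean of zero makes the metric undefined; the run is then reported
   non-converged rather than patched. Score SDs below ~1e-12 are treated
   as accumulation noise from summing identical doubles (the point-mass
   case) and reported as 0% error.

2. **Fuzzy inference engine.** A knowledge base of IF…THEN rules encodes
   the balanced-care view of which raw rates are *appropriate*. Each rule
   names a target variable, an optional antecedent (threshold comparisons
   over the area's simulated values, combined with all/any), an integer
   priority, and a piecewise-linear transform given by anchors
   `(x, y)` with strictly increasing `x` and `y ∈ [0, 1]`; evaluation is
   linear interpolation clamped outside the anchor range. Transforms may
   contain several rising and falling segments, i.e. multiple desirable
   zones. The highest-priority matching rule fires; an equal-priority
   conflict or a coverage gap is an error, never a silent choice.
   Transformed values are floored at `epsilon_floor = 0.001` so DEA
   inputs stay strictly positive (zero inputs make the VRS envelopment LP
   degenerate). This is rule-dispatched value transformation, not
   Mamdani/Sugeno fuzzy-set arithmetic — there is no membership overlap
   or defuzzification, by design.

   The *shipped default knowledge base* is a documented stand-in, not a
   validated expert rule set: one unconditional rule per variable, rising
   from the variable's reference minimum to its maximum for outputs, and
   unimodal (peaking at the reference mean) for inputs, encoding "both
   scarcity and oversupply relative to the regional norm are less
   appropriate". Real analyses should load a locally validated rule set;
   results under the default KB characterise the pipeline, not Andalusian
   policy.

3. **DEA.** Per replicate, each scenario forms one instance whose DMUs
   are the areas and whose matrices hold the transformed appropriateness
   values. The variable-returns-to-scale envelopment problem is solved
   radially per DMU with HiGHS, in both orientations: input
   (`min θ` s.t. `X'λ ≤ θx₀`, `Y'λ ≥ y₀`, `Σλ = 1`) and output
   (`max φ` s.t. `X'λ ≤ x₀`, `Y'λ ≥ φy₀`, `Σλ = 1`), with
   RTE = θ or 1/φ in [0, 1]. The slack-maximisation second stage is
   omitted — only radial scores are consumed — so weakly efficient units
   may score 1. Efficiency is flagged at `rte ≥ 1 − 1e-6`. Replicates are
   solved replicate-wise (65 DMUs per instance); pooling replicates as
   extra DMUs would change the meaning of the comparison set and was
   rejected. A brute-force simplex-grid oracle (λ enumerated at a fixed
   resolution, feasibility checked directly) provides an LP-independent
   check on tiny instances in the test suite.

4. **Indicators, comparisons, classification.** Eight global indicators
   per scenario/orientation, pooling all area × replicate cells: mean and
   variance of RTE; the statistical error above; P(efficient) and its
   complement; P(RTE > 0.75); stability; and normalised Shannon entropy
   over B = 10 equal-width bins on [0, 1], `100·(−Σ p_b ln p_b)/ln B`,
   empty bins contributing 0 (B is a package choice; entropy is reported
   on a 0–100% heterogeneity scale). Stability multiplies every simulated
   value by `1 + u`, `u ~ U(−δ, δ)` with δ = 0.01, re-runs fuzzy + DEA on
   the same replicates, and reports the share of cells whose RTE moved by
   at most ε = 0.01; δ = 0 is definitionally 100% stable. To bound LP
   cost the re-run uses at most the first 50 replicates. Scenario
   comparisons pool each scenario's cells: Kruskal–Wallis H with midrank
   tie correction (df = k−1, χ² p-value) and effect size
   `η²_H = (H − k + 1)/(n − k)`; post hoc two-sided Mann–Whitney pairs
   with Bonferroni adjustment `min(1, p·C(k,2))` and rank-biserial effect
   size `|1 − 2U/(n₁n₂)|` (absolute value, direction read from the
   means). Mean RTE per area is classified low (≤ 0.75), medium
   ((0.75, 0.9]) or high (> 0.9); the closed upper bounds follow the
   interval convention of the mapping thresholds. Classified levels and
   means can be joined onto any GeoJSON FeatureCollection by a
   configurable property; unmatched areas and polygons are reported, not
   dropped.

## Scenarios

Four expert-style scenarios describe successive integration of care
around the outpatient baseline, all sharing the outputs treated
prevalence and contacts in O9-O10: S1 outpatient only; S2 adds acute
hospital care (availability R2-O3, beds R2, R2-O3 workforce); S3 adds
health day care (availability D1-D4.1, places, D1-D4.1 workforce); S4 is
the union. Workforce categories (psychiatrists, nurses, psychologists,
non-clinical) enter as separate input columns by default; a switch sums
them into one workforce-capacity column per care group set, because DEA
discrimination degrades as the input count approaches the DMU count.
Healthcare assistants exist in the registry but are excluded from the
default scenarios' workforce list.

## Synthetic data generator

The generator emulates the published descriptives (mean, SD, min, max
over 65 areas) of the Andalusian adult mental-health network with
independent truncated-normal marginals. The location parameter is solved
(Brent) so the *truncated* distribution's mean equals the target — a
naive `truncnorm(loc=mean)` is biased wherever the bounds are asymmetric
— while the scale stays at the target SD, so realised SDs are somewhat
below target for strongly truncated variables. A one-dimensional latent
"management quality" per area, `latent ~ U(0,1)`, multiplies output
baselines by `1 + coupling·(latent − 0.5)` (default coupling 0.3,
moderate and clearly detectable without pressing outputs against their
bounds), giving the input→output dependence DEA needs to be
non-degenerate. Adult populations are log-normal (median ≈ 90,000,
σ = 0.55, clipped to [20k, 650k]), mimicking a region where a few urban
areas concentrate population. `split_capitals` partitions chosen areas
into 2–4 sub-areas whose counts and populations sum exactly, so capital
merging inverts it bit-exactly; a 65-area dataset split 4+4+3+3+3
reproduces the 77-raw/65-analysed configuration of the real network.

What the generator does **not** emulate: inter-variable correlations
beyond the single latent factor, spatial autocorrelation between
neighbouring areas, and the real (unpublished) expert knowledge base.
Passing tests therefore demonstrate correctness of the machinery under
controlled conditions, not reproduction of the real system's published
indicator values.

The deterministic 65-area fixture (`make_fixture("andalusia65")`)
additionally calibrates each variable's *sample* mean exactly to its
target by distributing the residual shift proportionally to each value's
headroom toward the bounds, so values never leave [min, max]; it serves
as a synthetic stand-in datasheet where the real one is not available.

## Numerical choices and degenerate inputs

- LPs solved with `scipy.optimize.linprog(method="highs")`; RTE clipped
  to [0, 1] against last-ulp solver noise; λ sums checked to 1e-6.
- Capital merging recomputes rates population-weighted from recovered
  numerators (`rate·pop/denominator`), never by averaging rates.
- Missing cells are load errors (naming row and column), not imputations;
  the modeled behaviour for incomplete services is exclusion.
- Rates and counts must agree within 1e-9 relative tolerance when both
  are present.
- RTE CSVs are written at full float precision and read back with
  round-trip parsing: near-1 scores differing by one ulp must not
  collapse into ties, or rank statistics change.
- Seeds: every stage derives an independent child stream from the run
  seed via `SeedSequence`; batches come from one sequential generator so
  raising the replicate cap only extends the same draw stream.

## Problem sizes

The shipped test-suite and acceptance-script runs use 65 areas with
batches of 100 replicates and a 500-replicate cap (convergence at the
2.5% threshold typically occurs at the first batch, with achieved errors
an order of magnitude below threshold), stability on 50 replicates, and
oracle cross-checks on ≤ 6-DMU instances at grid resolutions 0.02–0.05.
These sizes were chosen so a full run completes in minutes on one core
while leaving every statistic well inside its sampling tolerance.

## Known limitations

- Weakly efficient DMUs can score RTE = 1 (no slack stage).
- The stability and entropy definitions (perturbation scheme, bin count,
  pooling level) are package choices on a 0–100% scale; absolute values
  are comparable only within a fixed configuration.
- The default knowledge base is a stand-in; indicator levels under it do
  not estimate any real system's performance.
- No spatial statistics: cluster detection on the maps is left to the
  analyst.
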