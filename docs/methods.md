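# Methods

## Model

The scoring engine is a deterministic rule-based expert system over a
tripartite evidence network. Entities are mutated driver genes, druggable
target nodes, and molecularly targeted agents (MTAs); edges are `EvidenceRule`
objects of three kinds — `driver_function` (evidence for/against a gene's
functional relevance), `driver_target` (drugs hitting the target are
more/less effective in the presence of the driver) and `driver_mta` (the
agent itself is more/less effective in the presence of the driver). Each
rule carries a direction (positive/negative), an evidence class (clinical,
preclinical, in-silico, frequency), a journal-quality multiplier
(`source_weight`), and a tumor context.

A target node is identified by the *(gene, status)* pair, so the wild-type
and mutant forms of one gene are independent nodes and rules must name the
qualified node. We do not infer a node's activity status from the profile;
both forms can accumulate evidence for the same patient.

### Weighting

The weight of a rule applied to an observed alteration is

    |w| = base(class) · source_weight · f_tumor · f_alteration,

with sign from the rule direction. Defaults: base weights clinical 10,
preclinical 5, in-silico 1, frequency 2 (the published description fixes
only the hierarchy clinical > preclinical > in-silico, not the values;
`WeightConfig` exposes all of them). Alteration matching is graded exact
variant 1.0 > same class 0.75 > gene only 0.5 > different variant of the
same gene 0.25; tumor matching exact 1.0 > pan-cancer 0.75 > other tumor
0.5. A rule context with the same localization matches exactly when the
rule states no histology or the same histology; any other combination is
"other tumor". When several observed alterations of one gene match the
same rule, only the best match counts — one contribution per rule.
`source_weight` is accepted as any positive real; values outside the
conventional [0.5, 2.0] band are flagged as validation warnings, not
errors.

### Cascade

1. **Driver AEL**: sum over matching rules with the gene as subject;
   `driver_function` rules enter signed, `driver_target`/`driver_mta`
   rules enter at |w| — a resistance association is still evidence that
   the gene matters ("counts both ways"), and we take it at full weight.
   Genes with AEL > 0 are potential drivers; the threshold is strict.
2. **Target AEL**: signed sum of `driver_target` rules from potential
   drivers only. Frequency-class evidence never reaches this stage (it
   evidences driverhood, not drug response) — enforced as a knowledge-base
   invariant.
3. **MTA AEL**: `AEL(m) = Σ_d [S(d,m) + sign(S(d,m))·AEL(d)] + Σ_{t∈targets(m)} AEL(t)`,
   with `sign(0) = 0`: a driver whose direct associations with the agent
   cancel exactly contributes nothing, not its AEL. Negative-AEL targets
   deduct from the agents declared to hit them, which is what drives the
   resistance pattern (an inhibitor of a negatively scored target in a
   resistant profile lands below zero).

No closed-form aggregation is published for this system; the formulas above
are this package's committed reading of the verbal description, chosen to
reproduce its stated qualitative behaviors (positive-only driver gating,
aggregation over all drivers, sign-dependent addition/deduction of driver
and target scores, negative AELs for resistance-linked agents). Absolute
AEL values depend on the unpublished rule content and are not reproducible;
correctness of the engine is therefore property-based — exact additive
decompositions, linearity under rule duplication, equivalence with an
independent brute-force implementation, gating, monotonicity and scale
covariance — rather than value-based.

Tier bounds: low < 0, high > 1000, boundary values (exactly 0 or 1000)
assigned to intermediate; the published strict inequalities leave the
boundaries undefined. Rankings order by AEL descending with name ascending
as the tie-break, so output is total and deterministic. Scoring is linear
in the number of rules (one weight evaluation per rule, three linear
passes).

## Cohort evaluation

Patients are assigned to tiers by the AEL of the *administered* agent (not
the top-ranked one). Disease control = PR or SD; empty tiers report an
undefined rate (None), never zero. Kaplan–Meier estimation delegates to
lifelines; the curve median is the smallest observed time with S(t) ≤ 0.5
(within 1e-9 to absorb float noise in the product), undefined when the
curve never reaches 0.5. The log-rank test is computed explicitly
(hypergeometric variance, 1 df) because the reported hazard ratio is the
observed/expected estimator `(O1/E1)/(O2/E2)` with
`CI = exp(ln HR ± 1.96·√(1/E1 + 1/E2))`, which needs the per-group expected
counts; lifelines serves as the independent cross-check in the tests. A
group with zero events leaves the HR undefined (flagged) while the test is
still computed. The t-test defaults to Student's pooled-variance form
(Welch via flag); when both groups are constant with equal means the cohort
statistics report t = 0, p = 1 rather than failing. The PFS median split
uses the KM median of the whole cohort, ties going to the "below" group.
Top-agent concordance breaks AEL ties toward the alphabetically first name
and accepts equivalence groups of interchangeable agents (e.g. two
endocrine agents counted as one choice).

Out of scope by design: Cox regression and multivariable adjustment,
crossover handling for OS, and multiple-testing correction.

## Synthetic data

The production rule base is proprietary, so generators emulate its
structure. `generate_kb` draws a tripartite network with exact per-entity
rule counts; the defaults (12 genes, 20 target nodes, 40 agents, 1560
rules) are sized so that a typical simulated tumor of 3–4 altered genes is
touched by several hundred weighted interactions, putting agent AELs on the
thousands scale that the default tier bounds assume, with roughly
15/70/15% of agent scores in the low/intermediate/high tiers. The evidence
mix defaults to ~48% clinical / 46% preclinical with small in-silico and
frequency shares, mirroring the roughly half-and-half clinical/preclinical
composition described for the real base; 25% of rules are negative.
Profiles draw alterations from the rule subjects (so matching evidence
exists) with 1 + Poisson(mean − 1) alterations per patient, default mean
3.5 — the reported typical driver load.

`simulate_outcomes` ties outcomes to the administered agent's AEL:
PFS ~ Exponential(λ0·exp(−β·AEL/1000)), independent exponential censoring,
disease control ~ Bernoulli(logistic(−1.0 + 1.2·AEL/1000)), and
OS = latent PFS × LogNormal(μ=1, σ=0.25) with its own censoring draw. AEL
enters every effect divided by 1000 so coefficients are O(1) on the tier
scale. Defaults λ0 = 0.35/month, β = 1, censoring 0.05/month put the
intermediate tier's median PFS near 3 months, overall OS near 11 months,
and overall disease control near half — the scale of a heavily pretreated
advanced-cancer population. This exponential model is a test fixture
chosen as the simplest law consistent with a monotone AEL–PFS association,
not a scientific claim: it has no frailty, no tumor-type effect on hazard,
and treats censoring as independent, so passing tests demonstrate that the
pipeline *recovers a planted association and stays calibrated under the
null*, not that real cohorts behave this way.

All generators are pure functions of their parameters and seed; derived
seeds stay below 2^31.

## Numerical and testing choices

- Engine/oracle equivalence is asserted to 1e-9 absolute on networks of
  ≤ 50 rules; decompositions must sum *exactly* (same-order summation).
- The log-rank asymptotic p-value is validated against the complete
  permutation distribution (all 924 equal-size splits of a frozen n = 12
  survival fixture) within the Monte-Carlo 3σ band of a 10,000-draw
  permutation estimate. At these sample sizes the chi-square approximation
  itself deviates from the exact permutation p by a few hundredths for many
  datasets; the committed fixture is one where the approximation is
  accurate, and the hand-rolled permutation statistic is computed by an
  independent plain-loop implementation.
- Null calibration uses 200 replicates of n = 60 cohorts (KS test against
  uniform at α = 0.01); tier-separation power uses 100 replicates of
  n = 200. These sizes keep the whole statistical surface under a few
  seconds while leaving comfortable margins on both checks.
- Simulated AEL vectors for the calibration/power experiments are drawn
  uniform on [−1500, 3000], matching the span the default synthetic
  networks produce.

## Known limitations

- The engine reproduces the *form* of the published scoring system; its
  constants are this package's defaults, so absolute AELs are comparable
  only within one knowledge base and configuration.
- Variant matching is verbatim string comparison (no HGVS normalization);
  profiles enter at gene/protein level, with no genomic-coordinate
  annotation.
- Combination-therapy scoring, dose/toxicity modeling and automated rule
  curation are out of scope.
- The published trial cohort statistics can be reproduced by converting
  the deposited per-patient tables with `scripts/convert_shiva01.py` and
  running the cohort layer; the tables are not redistributed with the
  package, and without them that reproduction cannot run.
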