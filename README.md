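# dda — digital drug assignment

Evidence-network scoring of molecularly targeted agents (MTAs) from a
tumor's complete molecular profile, with a survival/response evaluation
layer for treated cohorts.

## The problem

Precision oncology usually pairs one drug to one predefined biomarker, but a
typical tumor carries 3–4 driver alterations whose joint effect on drug
response no single biomarker captures. Digital drug assignment (DDA)
replaces the single-biomarker lookup with a rule-based expert system: a
network of signed, weighted associations between mutated **driver** genes,
druggable **targets** (gene products, optionally qualified wild-type or
mutant), and **MTAs**, curated from published clinical, preclinical and
in-silico evidence plus alteration-frequency data. For each patient the
system aggregates every association touching the tumor's profile into an
*aggregated evidence level* (AEL) per driver, per target, and per MTA, and
ranks the MTAs.

## The score

Each evidence rule contributes a signed weight

```
w(rule) = ±  base(evidence class) · source_weight · f_tumor · f_alteration
```

where `base` encodes the evidence hierarchy (clinical 10 > preclinical 5 >
in-silico 1; frequency 2), `source_weight` is a journal-quality multiplier,
and `f_tumor`, `f_alteration` are matching weights in (0, 1] that discount
evidence whose tumor type or molecular alteration only partially matches the
patient's (exact variant 1.0 … different variant of the same gene 0.25;
exact tumor 1.0, pan-cancer 0.75, other tumor 0.5). The cascade then runs
in three passes:

1. **Driver calculation.** `AEL(d) = Σ signed function-evidence + Σ |drug/target-link evidence|` —
   sensitivity *and* resistance links both evidence a gene's functional
   relevance ("count both ways"). Genes with `AEL > 0` are *potential
   drivers*; everything downstream is gated on them.
2. **Target calculation.** `AEL(t) = Σ signed driver→target evidence` over
   all potential drivers.
3. **MTA calculation.** With `S(d,m)` the signed sum of direct driver→MTA
   evidence,

   ```
   AEL(m) = Σ_d [ S(d,m) + sign(S(d,m)) · AEL(d) ]  +  Σ_{t ∈ targets(m)} AEL(t)
   ```

   so a driver's own AEL is inherited with the sign of its net association
   with the drug, and negative-AEL targets deduct from their inhibitors.

MTAs are tiered by AEL: **low** (< 0), **intermediate** (0–1000), **high**
(> 1000). Every score carries its full additive decomposition, so any AEL
can be traced back to individual rules.

The cohort layer evaluates whether the score tracks clinical benefit in a
treated cohort: disease-control rates (PR+SD) by tier, Kaplan–Meier PFS/OS
with per-tier medians, pairwise log-rank tests with the observed/expected
hazard ratio `HR = (O1/E1)/(O2/E2)` and CI `exp(ln HR ± 1.96·√(1/E1+1/E2))`,
mean-AEL contrasts by t-test, and top-agent concordance.

Because the production rule base is proprietary, the package ships seeded
generators that emulate its structure (synthetic knowledge bases, patient
profiles, and outcome-linked cohorts with a controllable AEL effect), so
the whole pipeline is testable end to end with known ground truth.

## Worked example

```bash
dda simulate kb --seed 7 --out kb.json                      # synthetic evidence network
dda simulate profiles --kb kb.json --n 1 --seed 7 --out profiles
dda score --kb kb.json --profile profiles/SIM0001.tsv --out result.json
```

The simulated patient is a colorectal tumor with five alterations (APC
loss, an ERBB2 indel, INPP4B and STK11 variants). Scoring against the
1560-rule synthetic network prints:

```
scored SIM0001: 4 drivers, 20 targets, 40 MTAs
```

and `result.json` contains the ranked, decomposed scores:

```
drivers:                     top / bottom MTAs:
  ERBB2           394.88       fgfrtinib-021      1495.98  high
  STK11           368.64       cdkntinib-028      1427.35  high
  APC             326.46       fgfrparib-020      1158.51  high
  INPP4B          318.85       ...
                               brafrafenib-005    -373.81  low
                               brcarafenib-033    -601.55  low
```

All four mutated genes score positive, so all four gate the downstream
calculation; the top agents accumulate positive direct and inherited
evidence across several drivers (high tier, AEL > 1000), while the
bottom agents are dominated by resistance links and fall below zero (low
tier) — the pattern that flags a drug as contraindicated by the profile.

A treated cohort is analyzed the same way:

```bash
dda simulate cohort --kb kb.json --n 100 --seed 7 --out cohort.tsv
dda cohort --records cohort.tsv --out report.json --curves-dir curves/
```

`report.json` holds tier counts, DCR per tier, mean-AEL contrasts with
t-tests, KM medians and pairwise log-rank hazard ratios; `curves/` holds
the KM curves as TSV.

To analyze a real cohort, convert its per-patient table to the cohort TSV
layout (see `scripts/convert_shiva01.py` for the published trial deposit)
and run `dda cohort` on it.

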