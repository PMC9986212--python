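# Methods

This note documents the statistical models, default parameters, numerical
choices, and the limits of what the synthetic world can establish.

## The screening problem

The package targets the construction of ASD screening subscales from a
120-item parent-rated child-behavior inventory (items scored 0 = not true,
1 = somewhat/sometimes true, 2 = very/often true). Two informants —
mother and father — may each rate the same child, and either may be
missing. Children carry one primary classification out of eleven groups:
ASD, nine clinical comparison groups (ADHD, anxiety disorders, PTSD,
affective disorders, OCD and related, behavioral disorders, disorder NOS,
other classification, no classification), and a typically developing
group.

## Item registry

Item identifiers are the canonical inventory numbers 1..112; the eight
lettered sub-items of item 56 occupy identifiers 113..120, giving an exact
1..120 space. Only items appearing in the published subscale tables ship
with labels (the full instrument wording is proprietary); all other items
carry an empty label and syndrome `none`. Subscale membership is stored as
0/1 flags in a CSV shipped as package data and overridable by the user.
Two consistency rules are enforced at load time: the ASD-profile subscale
must equal the union of the Withdrawn/Depressed, Thought Problems and
Social Problems syndrome subscales, and WTP the union of the first two.

The packaged clinician-expert subscale contains **four** Social Problems
items. A well-known running-text tally of its composition lists three, but
that tally sums to 22 for a 23-item scale and is inconsistent with the
published item table and with every pairwise overlap count (12 with the
data-driven subscale, 7 and 8 with the Ooi and So subscales), all of which
the packaged registry reproduces exactly. One table entry prints a label
whose superscript syndrome marker contradicts it; the marker
(Anxious/Depressed) was followed, which resolves the entry to "Nervous,
high-strung, or tense" rather than "Nervous movements or twitching". No
overlap or composition count depends on that choice.

## Synthetic cohorts

Responses follow a latent-Normal threshold model. For child `c`, item `j`,
informant `i`:

```
L = delta_j * 1[group_c = ASD, j planted]
    + age_slope * (age_c - mean age) + sex_shift * 1[girl_c]
    + u_c + eps_ic,        u_c ~ N(0, tau^2),  eps_ic ~ N(0, sigma^2)
score = number of thresholds strictly below L
```

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | development-sample proportions (ASD ~16% of the clinical subsample, ADHD largest at ~44%, small TD group), scaled to a configurable total | the severe imbalance is a property worth stress-testing |
| mother / father present | 0.97 / 0.78 | the development sample's informant return rates (1573 mothers, 1260 fathers of 1625 children); a child losing both informants keeps the mother, so every child has at least one report |
| age | uniform 6-18 years | the instrument's age range |
| p(girl) | 0.37 | development-sample gender ratio |
| tau, sigma | 0.7, 0.7 | latent informant-informant ICC of 0.5, a typical mother-father agreement level |
| thresholds | (0.8, 1.8) | a null item is endorsed (score >= 1) by ~21% of reports and scored 2 by ~3%, a realistic clinical base rate for problem items |
| delta | 0.8 | a moderate planted shift; recovery tests use 2.5 (see below) |
| age_slope, sex_shift | -0.02/year, -0.15 | mild covariate effects so that adjustment is exercised; both configurable, including group-specific confounding studies via custom group tables |

No effect sizes for ASD item shifts are published for this instrument;
all values above are generator choices, not estimates. The generator does
**not** emulate comorbidity structure, site effects, informant main
effects, or DSM-IV/5 label drift.

The recovery acceptance test plants the packaged 15-item data-driven set
with `delta = 2.5` in a cohort of 1500 children. At that shift an ASD
report moves from a mean observed score of ~0.24 to ~1.6, and the smallest
comparison group (~31 children) still yields a Wald z far above the ~6.4
needed for power > 0.999 at `alpha = 0.001`; this makes exact set recovery
the expected outcome, so a failure indicates an implementation defect, not
bad luck.

## Mixed model

Scores are modelled as numeric in a linear mixed model with a child random
intercept — not an ordinal link model — matching the mean-comparison
language of the selection rule; the generator's thresholded responses
deliberately stress this (mildly misspecified) analysis. Fixed effects:
intercept, ten group dummies against the ASD reference, mean-centred age,
gender (girl = 1). Constant covariate columns (e.g. single-gender
fixtures) are dropped to keep the design full rank. Children with a single
informant contribute through the marginal covariance; nothing is imputed
or deleted.

Estimation is REML (ML behind a flag) with the variance ratio
`lambda = tau^2/sigma^2` profiled. Because the marginal covariance is
block-diagonal with blocks `sigma^2 (I + lambda J)`, Woodbury reduces every
GLS quantity to per-child sums; aggregating children by informant count
makes one criterion evaluation O(p^2) after a single O(n p^2) precompute
shared across all 120 items. The REML criterion is minimised over
`log lambda` on [-12, 9] (bounded scalar optimisation, `xatol = 1e-10`)
with an explicit boundary comparison at `lambda = 0`; estimates below
1e-8 collapse to the boundary. When no child has two informants the ratio
is unidentified (the criterion is flat) and the fit falls back to
`tau^2 = 0` with a warning. The test suite cross-checks parameters,
variance components and standard errors against statsmodels `MixedLM` and
against a dense-matrix REML grid oracle.

Inference is a two-sided Wald test with a Normal reference (no
Satterthwaite correction) — adequate for the thousands-of-children regime
the pipeline targets and anti-conservative for very small samples, which
the null-calibration test bounds (empirical per-contrast rejection rate at
`alpha = 0.001` stays below 0.005 over 2000+ null item fits with 30
children per group). A verdict "ASD scores higher than group g" requires
both `p < alpha` and a negative group-minus-ASD contrast; sidedness is
therefore conservative relative to a one-sided test at the same level.

## Selection rules

The 70% criterion is the integer rule `>= ceil(0.7 * 10) = 7` of 10
comparison groups; both the integer and the fraction are configurable and
the integer wins when both are given. Items whose fit did not converge are
excluded, not imputed. The clinician rule requires a complete binary
matrix and counts column votes against the threshold (11 of 15 by
default); `vote_fraction` reports the threshold as a percentage to two
decimals (73.33).

## Scoring and reliability

A child's subscale score is the mean over available informants of the
per-informant raw sum. Within an informant's report a missing item scores
0 (no proration), but an informant missing more than 10% of a subscale's
items (configurable) is dropped for that scale. Cronbach's alpha uses
informant-averaged item scores pooled over the sample at hand, sample
variances with denominator n-1, and listwise deletion of children with a
fully missing item. Band edges 0.60/0.70/0.80/0.90 split poor /
questionable / acceptable / good / excellent with closed-open intervals;
values below 0.50 are also reported as poor.

## ROC machinery

AUC is the tie-aware Mann-Whitney probability, computed via midranks; the
standard error and the Wald 95% CI (clipped to [0, 1]) come from the
DeLong structural components. Band edges 0.70/0.80/0.90 split poor / fair
/ good / excellent. The paired DeLong test aligns children by identifier,
requires identical case/control membership, and degenerates gracefully
(identical curves report z = 0, p = 1). The Hanley-McNeil test recomputes
both standard errors from the AUCs and class sizes with
`Q1 = A/(2-A)`, `Q2 = 2A^2/(1+A)`.

Cut-offs: candidate thresholds are midpoints between adjacent distinct
scores plus +-infinity, classification is `score >= cutoff -> positive`
(the screening convention). The subclinical cut-off is the largest
threshold with sensitivity >= 0.80 (no rounding window — deterministic and
monotone in the target). "Optimal equilibrium" for the clinical cut-off is
maximum Youden's J with ties broken toward the lower threshold (favouring
sensitivity); minimising |sens - spec| is available via
`equilibrium="balance"`. Note the tie-break can legitimately place the
clinical cut-off below the subclinical one on coarse integer scores where
J is flat; the rules are applied exactly as stated rather than forcing an
ordering. Cut-offs are derived per gender x age-band stratum (child =
under 12, adolescent = 12+, configurable); pooled rates apply each
stratum's own cut-off and then pool the classification counts
(stratify-then-pool).

## Pipeline

Development fits all items, applies both rules, and validates every
configured subscale on the development cohort. Cross-validation applies
the frozen subscales and the development cut-offs; nothing is re-selected
or re-thresholded downstream (a test asserts the applied thresholds equal
the development ones). DeLong comparisons are used within the ASD-target
family (shared cases/controls); Hanley-McNeil against the DSM-oriented
subscales, whose case groups differ (affective disorders, anxiety
disorders, ADHD, behavioral disorders). The simulated world has a single
behavioral-disorders group, which serves as the ODD-subscale target; the
conduct-disorder target has no group of its own and that subscale is
reported as unavailable — mirroring sparse real samples. All randomness
descends from one root seed through spawned seed sequences (every derived
seed below 2^31), making full runs bitwise reproducible.

## What a green test establishes — and what it does not

The synthetic world shares the analysis's structure (nesting, missingness,
ordinal scores, group imbalance) but plants a clean, homogeneous ASD
shift on a known item set. Recovery and calibration tests therefore
establish the correctness and statistical behaviour of the *procedure* —
they do not validate any empirical subscale against real children, and
the high AUCs/alphas in planted runs say nothing about field performance.
The DSM-oriented subscales discriminate poorly in the simulated world by
construction (no shifts are planted for their target groups); they are
included to exercise the independent-curves comparison arm, not to emulate
their empirical accuracy. The packaged registry algebra, by contrast, is
exact and is asserted against the published counts.
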