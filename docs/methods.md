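# Methods

## The rule and the validation problem

The ABC score assigns one point each for age ≤ 70 years (A), a witnessed
arrest with no-flow time ≤ 5 minutes (B), and a shockable first rhythm
(VT/VF) or bystander public-access defibrillation (C). Both numeric
thresholds are inclusive; no-flow time is accepted as any non-negative real
and compared to 5.0 without flooring (sub-minute records simply compare as
given). An unwitnessed arrest scores B = 0 and needs no no-flow time. PAD
grants C regardless of the recorded rhythm — the two criteria are an OR, not
a tiebreak — so a record with PAD and a missing rhythm is still scorable.
A first rhythm recorded as "spontaneous circulation" in a patient without
prehospital ROSC is retained and scores C = 0 unless PAD was performed.

Validation treats the score as an ordinal marker of a binary outcome:
favourable neurological status (CPC 1–2 at one month) versus CPC 3–5.

## Cohort selection

The funnel retains records satisfying, in this order: resuscitation
attempted and age present and ≥ 18 (inclusive); internal (medical) cause;
ABC score computable; outcome known; no prehospital ROSC; outside the
derivation region (Kanto); arrest year inside one of the analysed guideline
eras (2007–2009 → 2005 guidelines, 2012–2014 → 2010, 2017–2019 → 2015; all
other years are transition periods and excluded). Each excluded record is
tallied once, at the *first* filter it fails, which makes the exclusion log
deterministic and invariant to input order. "Score computable" requires age
and witnessed status, a no-flow time whenever witnessed, and a first rhythm
unless PAD was performed; a record with PAD but missing witnessed status is
still excluded, because B cannot be resolved.

The source ordering of the funnel steps is a package convention (the
original report draws a flow chart without specifying first-failure
attribution); only the per-step tallies depend on it, never the retained
cohort.

## Reconstruction from cumulative counts

Published validation tables report, per guideline group, the cohort size N,
the total favourable count P, and pairs (n_t, pos_t) at the thresholds
score ≥ 1, ≥ 2 and = 3. These determine the full 4×2 score-by-outcome table
by successive differences: n₀ = N − n₍≥1₎, n₁ = n₍≥1₎ − n₍≥2₎,
n₂ = n₍≥2₎ − n₍=3₎, n₃ = n₍=3₎, and identically for the favourable counts.
The recovered stratum sizes agree *exactly* with the independently printed
per-score patient counts in all three groups — nine equalities that pin the
reconstruction. The forward map (strata → cumulative) is implemented too and
the round trip is property-tested.

## Test characteristics and intervals

At threshold t, predicted-positive means score ≥ t, giving tp = Σ_{s≥t}
pos_s and the usual 2×2 identities (tp+fn = P, fp+tn = N−P,
LR+ = sens/(1−spec), LR− = (1−sens)/spec). Proportions carry binomial
intervals; the method is pluggable — Clopper–Pearson exact (default, via the
beta quantiles), Wilson, or Wald — because the original analysis does not
state its method and the printed bounds are not exactly recoverable under
any of them. Point estimates are exact; interval bounds are checked against
the printed ones only to ±0.5 percentage points. Likelihood-ratio intervals
use the delta method on the log ratio (Simel):
exp(ln LR ± z·SE), SE² = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn) for LR+ and the
fn/tn analogue for LR−. A zero false-positive cell makes LR+ infinite and is
raised as an explicit error rather than returned as an overflow. Percentages
are printed at two decimals with half-up rounding, mirroring clinical-table
convention; internal values keep full precision.

## ROC, AUROC and the Youden cutoff

The four-level score yields a five-point ROC (both corners plus one point
per threshold), oriented so that higher scores predict the favourable
outcome. The AUROC is computed both as the trapezoidal area and in the
tie-corrected rank (Mann–Whitney) form

    AUROC = [ Σ_{s>s′} pos_s·neg_{s′} + ½ Σ_s pos_s·neg_s ] / (P·(N−P)),

and the two must agree to 1e-12 (an internal consistency assertion; the two
are algebraically identical for a monotone ordinal marker, which is also why
it is immaterial whether the score or any monotone probability transform of
it is used). The Youden index J = sensitivity + specificity − 1 is evaluated
at t ∈ {1,2,3}; ties break toward the **larger** threshold, preferring the
more specific cutoff — the natural reading when the score gates a
resource-intensive therapy. Hanley–McNeil AUROC intervals are available as
descriptive output only.

## Calibration

Calibration is tabular/graphical only: per occupied score stratum, a
user-supplied predicted CPC 1–2 probability is set against the observed
proportion pos_s/n_s with its binomial interval. Predicted values are a
required configuration input (typically derivation-cohort rates, which are
not recoverable from the validation report); an example config ships with
the package. No recalibration (intercept/slope updating) is performed.

## Synthetic registry generator

No public accession exists for the nationwide registry, so the package
includes a seeded generator of Utstein-style cohorts used by the tests and
available as study material. Generation is **stratum-first**: each record's
score is drawn from a configured 4-way marginal, the component pattern
realising that score is drawn uniformly over the feasible patterns (e.g. a
score of 2 picks two of {A,B,C}), concrete fields are then sampled
consistently with the pattern, and the CPC category is drawn from per-score
probabilities (p₁₂, p₃₄, remainder death). Stratum-first construction makes
the score marginal and the per-score outcome gradient — the only quantities
the discrimination pipeline consumes — match their targets in expectation by
construction; solving instead for a dependence structure among independently
generated components would require correlations the source data do not
report.

Bundled configs `g2005`/`g2010`/`g2015` use the exact score marginals and
per-score CPC 1–2 probabilities of the reconstructed tables (e.g. 2005:
marginal 0.5376/0.3602/0.0856/0.0166, p₁₂ ≈ 0.0018/0.0058/0.0293/0.0954)
with n = 160,000, close to the real cohort sizes; the implied tie-corrected
AUROCs are 0.798/0.822/0.828. Component-level details are chosen once to be
registry-plausible and are irrelevant to the discrimination surface: ages
are truncated normals per A-arm (old arm centred at 81, matching the
registry's median of ~79–81); among B = 0 records 21% are witnessed with a
6–30 min exponential-tail no-flow time, reproducing an overall witnessed
rate near 38%; the PAD share of C = 1 follows each era's printed PAD counts
(rising from ~7% to ~18%); CPC 1 vs 2 and 3 vs 4 split 50/50 by default.
The p₃₄ defaults are uninformative plausible values — per-score CPC 3–4
counts are not published — and never enter the favourable-outcome analyses.

Contamination (records built to fail exactly one funnel step) is appended
after the eligible draw, each class with a Binomial(n, rate) count on its
own RNG substream spawned from the root seed, so enabling contamination
never perturbs the eligible records. Every record's intended fate is encoded
in its id, letting tests check the funnel's tallies against the generator's
bookkeeping exactly.

`expected_auroc` evaluates the rank formula on the *expected* cell masses
π_s·p_s and π_s·(1−p_s) — the closed-form AUROC of the generating
distribution — and is cross-checked against a 10⁶-draw Monte-Carlo
simulation in the tests.

What passing the synthetic tests does **not** show: the generator imposes no
inter-variable correlation beyond what the score strata force (no age–witness
dependence, no secular trend within an era, no regional structure), its
component distributions are plausible rather than estimated, and real
registry exports will differ in missingness patterns and coding. Results on
synthetic cohorts validate the *pipeline*, not the score's clinical
performance.

## Numerical choices and problem sizes

- Proportion CI default: Clopper–Pearson (conservative, exact coverage);
  level 0.95 throughout unless overridden.
- Rounding for printed-style output: decimal half-up, two decimals.
- Degenerate inputs: an empty outcome class raises a named error everywhere
  (characteristics, ROC); empty strata are flagged and skipped in
  calibration output rather than erroring.
- Test problem sizes: property tests use cohorts ≤ 200 for the O(n²) AUROC
  oracle; parameter-recovery and convergence checks use 10⁵-record cohorts
  and a 10⁶-draw count-level simulation; the end-to-end simulation check
  uses one 160,000-record cohort — sizes chosen to keep the full suite
  around ten seconds while leaving the binomial bands tight enough to
  detect miscalibration.

## Known limitations

- The funnel's first-failure attribution order is a convention; per-step
  tallies are not comparable to flow-chart boxes produced under a different
  order.
- CI methods for the original printed intervals are unknown; only point
  estimates are treated as exact.
- Records with missing witnessed status but PAD performed are excluded
  (B unresolvable); an alternative policy (impute B = 0) would retain them
  and is not implemented.
- No paediatric scoring, no re-derivation or re-weighting of the score, no
  DeLong between-group AUROC comparison, no multivariable or survival
  modelling.
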