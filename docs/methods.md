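# Methods

This note documents the models, conventions, and design choices behind the
package, in the order a reader meets them: the score and its decision rule,
the diagnostic and survival estimators, the repertoire analytics, the
synthetic-data generators, and the deterministic landmark fixture. It closes
with numerical conventions and known limitations.

## The CX3CR1 score

The biomarker is the frequency of CX3CR1+ cells among circulating CD8+
T cells, measured by flow cytometry at baseline (week 0) and on treatment.
Because pretreatment frequencies vary widely between patients (roughly 6–76%),
the analysis works on the *percent change from baseline*,
`100 (v − b)/b`, and summarises each patient at a landmark week W by the
**maximal** percent change over all post-baseline samples at or before W.
The maximum is the right summary for a marker whose expression is effectively
irreversible once CD8+ T cells differentiate: a rise that persists is signal,
and the running maximum is monotone in W by construction, which the tests
assert per patient.

Conventions, each of which is deliberate:

- the ≥ 20% cutoff is **inclusive** (a score of exactly 20 is positive);
- a zero baseline raises an error rather than returning infinity;
- negative maximal changes are retained (non-responders commonly decline);
- a patient with no post-baseline sample by W is **unevaluable at W** and is
  excluded from that landmark's diagnostics — no imputation. This is what
  makes the week-3 analysis run on 27 of 36 patients in the fixture;
- all samples with `0 < week ≤ W` enter the week-W maximum, not only the
  week-W sample.

## Diagnostic evaluation

Confusion-table rates use Jeffreys-prior binomial intervals
(Beta(x+½, n−x+½) central quantiles, lower forced to 0 at x = 0 and upper to
1 at x = n). Odds ratios use the Woolf log-scale interval with the exact
normal quantile (1.959964…); with any empty cell the Haldane–Anscombe +0.5
correction is applied to all four cells and the result is flagged. The
two-sided Fisher exact p sums hypergeometric probabilities no larger than the
observed table's (the `fisher.test`-style rule), delegated to scipy and
verified against full enumeration in the tests.

The continuous-score path computes the empirical ROC (thresholds at the
observed scores; ties get half credit), the DeLong structural-components
variance for the AUC (Wald interval truncated to [0, 1]; a zero variance
collapses the interval and is flagged), the Youden-optimal cut-point
(candidates are the distinct observed scores under the rule
`score ≥ cutoff → positive`; exact ties in J favour the smallest cutoff,
i.e. sensitivity), and a univariate logistic fit by Newton/IRLS
(log-likelihood tolerance 1e-10, 100 iterations; complete separation is
detected up front and flagged instead of fitted). Because the logistic
transform is monotone, the ROC of the fitted probabilities coincides with the
empirical ROC of the raw score (up to orientation when the fitted slope is
negative), which the tests verify numerically.

Mann–Whitney U uses the exact null distribution when both groups have n ≤ 8
and the tie-corrected normal approximation otherwise.

## Survival

Kaplan–Meier curves come from lifelines' product-limit fitter; the median is
the smallest time with S(t) ≤ 0.5 and is reported as undefined when the curve
never reaches 0.5. The log-rank statistic is tabulated directly from the
pooled risk sets (hypergeometric variance; ties at an event time are one
risk-set step; subjects censored at t remain at risk at t), and the same O/E
table yields the Mantel–Haenszel hazard ratio `(O_A/E_A)/(O_B/E_B)` with
interval `exp(ln HR ± z √(1/E_A + 1/E_B))`. This is the hazard ratio
convention of Prism-style log-rank output; a Cox model is intentionally not
implemented. The O/E estimator is known to shrink toward 1 when follow-up is
long enough for the risk sets to diverge strongly; under study-like censoring
(uniform on [0, 35.5] months) it recovers a true exponential ratio of 0.3
within ±0.05 at n = 2000, which is how the tests validate it.

## Repertoire analytics

Rearrangement tables are parsed from ImmunoSEQ-style TSV (configurable
headers). Non-productive rows (status other than "In") are filtered out and
frequencies renormalised over the retained template counts. Diversity and
overlap statistics key clonotypes by **nucleotide** sequence; the
similarity-clustering workflow keys by **CDR3 amino-acid** sequence.

- **Clonality** = 1 − H/ln R (H the Shannon entropy of clone frequencies,
  R the number of unique clonotypes); undefined (NaN) at R = 1.
- **Overlap** defaults to Morisita–Horn on frequencies,
  `2 Σ p q / (Σ p² + Σ q²)` over the union of clonotypes — 1 iff the
  frequency vectors are identical, 0 iff the supports are disjoint. The
  classic count-based Morisita index (Simpson-corrected, can slightly exceed
  1) is available behind a flag, since the platform convention is ambiguous.
- **Gini / Lorenz**: the Gini index is computed from the sorted-frequency
  closed form of the mean absolute difference; the Lorenz curve sorts clones
  ascending and the identity `G = 1 − 2 × (trapezoid area under Lorenz)` is
  exact for this discretisation and asserted to 1e-9.
- **Alignment distances**: global Needleman–Wunsch (Biopython's
  PairwiseAligner) under PAM10 with a flat 30-per-gap-position penalty (no
  separate extension). The pairwise distance is self-score-normalised,
  `d = 1 − S_ab/√(S_aa S_bb)`: symmetric, 0 at identity, and allowed to
  exceed 1 for pairs with negative cross-score. This normalisation is an
  interpretation — the clustering literature the workflow follows does not
  pin one down — and is therefore isolated in a single function.
- **PAM10 matrix**: no canonical PAM10 file ships with the installed
  toolchain, so the package derives one by the Dayhoff chain from the
  high-precision 1978 relatedness-odds matrix (MDM78): odds → column-
  normalised 250-PAM mutation matrix → matrix logarithm → per-PAM rate →
  10-PAM transition matrix → symmetrised 10·log10 odds, rounded to integers.
  The result is frozen at `src/cx3score/data/pam10.txt`, regenerated only by
  `scripts/make_pam10.py`, and checksummed at load time. Its diagonal
  (10–20) dominates every off-diagonal entry (≤ 0), which guarantees the
  identity alignment is optimal and distances are non-negative.
- **UPGMA**: average linkage with merge height = half the linkage distance
  (midpoint convention), so cophenetic distances reproduce an ultrametric
  input exactly. Equidistant candidate pairs are broken by the smallest leaf
  label, making the topology invariant to input order. Leaf weights carry
  clone frequencies for frequency-weighted dendrograms; output is Newick.
- **Motif sharing** between two top-N lists is exact string matching of
  CDR3 amino-acid sequences; homology-based grouping is available by cutting
  the dendrogram at a user threshold but is not the default.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes; they
are fixed, not tuned per experiment.

**Baseline.** Frequencies are scaled logit-normal on [6.1, 76.3] with median
32.3%: `b = low + (high − low)·expit(N(μ, 1))`, where μ = logit((32.3 −
low)/(high − low)) makes the median exact in closed form (the median of a
monotone transform is the transform of the median). The logit-normal gives
bounded support with a controllable median.

**Trajectories.** Patient i's measured frequency at week w is

```
v_iw = clip( b_i · (1 + (m_i − 1) · r_w), 0, 100 ),   r_w = min(w/6, 1)
```

a rise to an on-treatment plateau reached by the second post-baseline visit.
The patient's realized multiplier is `m_i = E_i + η_i`: `E_i` the arm effect
(default centers ×1.5 for responders, ×1.0 for non-responders; optional
lognormal between-patient heterogeneity via the third `responder_effect`
parameter, default 0), and `η_i ~ N(0, noise_cv)` a **single patient-level
measurement error of the follow-up/baseline ratio** (default sd 0.15).

Two modelling decisions deserve emphasis. First, the noise is one draw per
patient, i.e. repeat measurements of a trajectory are treated as fully
correlated: flow-frequency measurements of the same patient share gating and
assay idiosyncrasies, and the within-patient correlation of repeated
measurements is otherwise unconstrained by the available information. Under
i.i.d. per-visit noise the maximal percent change would be an inflated order
statistic — a +5% arm would *measure* near +22% at realistic noise — which
contradicts the analysis the generator exists to support. Second, the error
is additive on the ratio scale (symmetric, sd proportional to the baseline
level) rather than multiplicative lognormal; symmetric equal-spread arms put
the optimal discrimination threshold at the midpoint of the arm effects, so
a +35%/+5% design recovers a Youden cut-point near +20%, consistent with the
reported optimal range of 15.5–21.2%. With `noise_cv = 0` and a fixed ×1.5
responder effect every responder's maximal change is exactly +50.

**Missingness and labels.** Each patient loses the week-3 sample with
probability `week3_missing_fraction` (default 0.25, matching 27/36 observed).
Responders are labelled CR (25%) or PR; non-responders SD or PD. PD-L1 TPS is
drawn ≥50% with probability 31/36.

**Survival.** PFS and OS times are exponential with medians indexed by the
patient's realized rule-positive status (defaults: PFS 19.5 vs 5.7 months,
OS 36.0 vs 8.6), censored independently and uniformly on
[0, max_followup = 35.5] months. The OS default for the positive arm exceeds
the follow-up horizon, so its KM median is typically undefined — mirroring a
"not reached" readout.

## Repertoire generator

Clone sizes follow a discretised rank power law (`rank^(−exponent)`,
largest-remainder allocation summing exactly to the template total, minimum
one template per clone; the size profile is deterministic given the spec,
randomness enters through sequence identities). CDR3 amino-acid sequences are
"CASS" + uniform interior + "F" with lengths in the configured range;
nucleotide keys are random codon-length strings; an optional non-productive
spike-in adds out-of-frame rows. Paired repertoires share exactly
`round(f · min(n_clones))` clonotype sequences; with `couple_counts=True`
shared clones also occupy the same abundance ranks in both repertoires
(equally expanded in both compartments), which makes the expected
Morisita–Horn overlap rise essentially linearly from 0 to 1 in f. With
independently placed shared clones the overlap still rises in expectation,
but single pairs are noisy because the index is dominated by the largest
clones.

## The landmark fixture

The deterministic 36-patient fixture encodes per-patient positivity onset
weeks chosen so that the score pipeline reproduces the published per-week
confusion counts exactly: TP/FP of 5/1 (week 3, among the 27 with samples),
8/3, 11/3, and 12/3, with 13 responders, 23 non-responders, and PD-L1
TPS ≥ 50% for 31 patients. The patient-to-onset assignment is not unique
given only the marginal counts; patients are assigned by sorted index (the
first responders turn positive earliest), which is reproducible and — because
printed TP and FP counts are non-decreasing across weeks — automatically
consistent with the running-maximum monotonicity of the score. Baselines are
30.0% with follow-ups at 45.0% (+50, positive) or 33.0% (+10, negative).
Survival fields are filled with deterministic synthetic times for pipeline
completeness; no published survival number is encoded.

## Numerical conventions

- Percentages live on the 0–100 scale at interfaces; proportions appear only
  inside the diagnostics internals.
- Normal quantiles are exact (`norm.ppf`), never the rounded 1.96 — this is
  what reproduces the printed Woolf bounds 1.5 and 5.3. The week-9 upper
  bound computes as 253.77 against a printed 253.8; the residual ±0.1 traces
  to rounding or software detail in the source analysis and is accepted.
- Youden ties use a 1e-12 slack so exact float ties resolve to the smallest
  cutoff deterministically.
- JSON reports are written with sorted keys and no timestamps; identical
  inputs give byte-identical outputs.
- Problem sizes in the test and acceptance runs (10,000-patient calibration
  cohorts, 100 × n=500 recovery replicates, 1000 permutations/enumeration
  trials, n = 2000 hazard-ratio recovery) were chosen so the full suite
  completes in well under a minute each while leaving Monte-Carlo margins
  comfortably wider than the asserted tolerances.

## What the synthetic data do and do not show

The generators reproduce the *structure* the estimators assume — bounded
baselines with the right median, plateau trajectories straddling the rule,
missingness, rule-linked exponential survival, power-law clone sizes with
controllable sharing. They do not emulate visit-time jitter (nominal protocol
weeks stand in for the real 3–6-week windows), within-patient visit-to-visit
measurement wobble (see the correlation argument above), non-exponential
hazards, informative censoring, or V/J-gene usage structure. Passing tests
therefore demonstrate correctness of the estimators and pipeline under these
idealised conditions, not clinical validity on new data; the published
survival medians and repertoire overlap values are not reproducible without
the patient-level data and are deliberately not asserted anywhere.
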