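# cx3score

Dynamic blood-biomarker analysis for immune-checkpoint-inhibitor (ICI)
response, built around the **CX3CR1 score**: the percent change from baseline
of the CX3CR1+ fraction among circulating CD8+ T cells during anti-PD-1
therapy. CX3CR1 marks stable effector differentiation of CD8+ T cells, so a
sustained on-treatment rise of the CX3CR1+ subset in blood is an early,
assay-friendly correlate of objective response — unlike transient markers
such as Ki-67, and unlike tissue-bound baseline markers such as PD-L1 tumor
proportion score (TPS).

The package is for biostatisticians and translational immunologists who want
to evaluate an on-treatment longitudinal biomarker end to end: scoring,
diagnostic performance with exact-style intervals, survival by biomarker
group, and the TCR-repertoire similarity analytics used to argue that the
circulating subset mirrors the tumor-infiltrating repertoire.

## The score and decision rule

For patient *i* with baseline frequency *b\_i* (% of CD8+ T cells) and
follow-up measurements *v\_iw* at weeks *w*, the per-visit score is

```
score_iw = 100 × (v_iw − b_i) / b_i
```

and the **CX3CR1 score at landmark week W** is the maximal percent change
by that landmark, `max { score_iw : 0 < w ≤ W }`. The decision rule calls a
patient positive when the score reaches **+20% (inclusive)**. Patients with
no post-baseline sample by W are unevaluable at that landmark and are
excluded there rather than imputed.

Around the score the package provides:

- **diagnostics** — confusion-table rates with Jeffreys (Beta(x+½, n−x+½))
  95% intervals, Woolf odds-ratio intervals (Haldane–Anscombe fallback),
  two-sided Fisher exact test, empirical ROC with DeLong AUC interval,
  Youden-optimal cut-point, univariate logistic fit, Mann–Whitney U;
- **survival** — Kaplan–Meier curves and medians, log-rank (Mantel–Cox)
  test, and the (O/E)-based Mantel–Haenszel hazard ratio;
- **repertoire** — ImmunoSEQ-style TSV parsing with productive filtering,
  clonality (1 − Pielou evenness), Morisita–Horn overlap (classic Morisita
  behind a flag), Gini index and Lorenz curve, top-N CDR3 selection,
  PAM10/gap-30 global alignment distances, frequency-weighted UPGMA
  dendrograms (Newick output), and exact-match clonotype sharing;
- **synthetic data** — generators for cohorts and clonally expanded
  repertoires emulating the study conditions, plus a deterministic
  36-patient fixture that reproduces the published landmark classification
  counts exactly (see `docs/methods.md`).

## Worked example

The deterministic fixture reconstructs the 36-patient landmark table
(13 responders / 23 non-responders, 27 with a week-3 sample) and runs it
through the actual score → diagnostics pipeline:

```
python analysis/02_landmark_performance.py
```

prints

```
column       pdl1_tps_ge50  week3  week6  week9  week12
metric
ppv                   38.7   83.3   72.7   78.6    80.0
npv                   80.0   76.2   80.0   90.9    95.2
sensitivity           92.3   50.0   61.5   84.6    92.3
specificity           17.4   94.1   87.0   87.0    87.0
accuracy              44.4   77.8   77.8   86.1    88.9
week3: OR 16.0 (1.5-171.2), Fisher p 0.01518
week9: OR 36.67 (5.3-253.77), Fisher p 3.726e-05
```

Reading: by week 12 the ≥20% rule identifies 12/13 responders (sensitivity
92.3%) while only 3/23 non-responders cross it (specificity 87.0%), and the
rule's accuracy (88.9%) is double that of the baseline PD-L1 TPS ≥50%
comparator (44.4%), whose specificity collapses at 17.4%. The week-3 rule —
only three weeks into therapy, on the 27 patients with a sample — already
separates responders (odds ratio 16.0, Fisher p ≈ 0.015).

The other drivers follow the same pattern: `analysis/01_simulate_cohort.py`
generates a synthetic cohort anchored at the published baseline distribution
(median 32.3% on 6.1–76.3%), `analysis/03_survival_analysis.py` contrasts
rule-positive vs rule-negative survival (e.g. PFS medians 15.9 vs 5.2 months,
HR 0.35 at n = 300 under the generator defaults), and
`analysis/04_repertoire_similarity.py` traces Morisita–Horn overlap from 0 to
1 along a clonotype-sharing gradient.

A CLI mirrors the library (`cx3score simulate-cohort | score | perf |
survival | repertoire-stats | immunomap | run`); exit code 2 flags validation
errors.

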