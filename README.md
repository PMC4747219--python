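# sagp-risk

Survival screening of **sense-antisense gene pairs** (SAGPs) in tumor
cohorts: correlation-based pair screening, optimal-cutoff risk partitioning
on the expression plane of a gene pair (with axis rotation), voting-based
patient stratification into low-/high-risk subgroups, and the downstream
differential-expression, enrichment, promoter-overlap and copy-number
statistics. The package is aimed at computational biologists who work with
bulk expression cohorts carrying time-to-event follow-up (e.g. disease-free
survival in breast cancer) and want a tested, reusable implementation of
this pair-centric prognostic methodology, exercised end-to-end on synthetic
cohorts with known ground truth.

## The method

An SAGP is a pair of protein-coding genes transcribed from opposite strands
of a shared locus (divergent, convergent or embedded orientation). The
pipeline:

1. **Screening.** Within a clinical subgroup, keep pairs whose partners'
   expression is significantly correlated (Kendall τ_b, two-sided p < 0.05),
   intersected across cohorts. Pair sets are compared between tissue classes
   with two-sample Kolmogorov–Smirnov tests on the τ distributions.
2. **1-D DDg (data-driven grouping).** For a single gene with standardized
   expression x, search cutoffs c over the empirical quantiles
   q ∈ {0.10, 0.15, …, 0.90} and score the split g = 1{x > c} by the Wald
   statistic (β̂/se)² of a univariate Cox proportional-hazards fit
   (Breslow ties); keep the cutoff minimising the Wald p.
3. **2-D DDg / rotated 2-D DDg.** For a pair, cutoffs (c¹, c²) on the two
   (optionally rotated) axes split the plane into four quadrants; a *design*
   assigns a subset of quadrants to the high-risk sector and a *sub-design*
   orients the labels. Plain 2-D DDg searches the 5 two-cutoff designs (10
   sub-designs); the rotated variant searches all 7 quadrant bipartitions
   (14 sub-designs) × 16 rotation angles θ ∈ {0°, 5.625°, …, 84.375°}. The
   fitted partition minimises the Cox Wald p over the whole grid.
4. **Signature selection.** Training runs independently in ≥ 2 cohorts; a
   pair enters the signature only if it is *synergistic* (its best 2-D p
   beats both partners' best 1-D p in every cohort) and one cohort's optimal
   configuration — design, sub-design, angle, quantile-scale cutoffs — is
   significant when applied unchanged in every training cohort
   (Bonferroni-corrected over the candidate configurations).
5. **WVG voting.** Each selected pair votes high/low risk per patient; the
   majority (most significant pair breaking ties) gives the final
   stratification, evaluated by Cox Wald p, prognostic accuracy and (across
   re-measurements) Cohen's κ.
6. **Downstream.** Welch-t differential expression between the voted
   subgroups with Storey q-values, cross-cohort intersection,
   hypergeometric gene-set enrichment; strand-aware −450/+50 bp proximal
   promoters vs ChIP peaks (Fisher's exact, with the bidirectional-promoter
   doubling rule), and SNP-based per-gene copy-number means compared by
   Wilcoxon matched pairs.

## Worked example

Simulate a two-cohort study (250 tumors + 60 normals per cohort; 12
survival-informative SAGPs, 12 correlated-but-uninformative SAGPs, 12
gene-neighbour controls, 300 background genes) and run the full analysis:

```python
from sagp_risk.pipeline import run_study
from sagp_risk.synthetic_data import SimulationConfig, simulate_study

bundles, pairs, truth = simulate_study(SimulationConfig(seed=3))
result = run_study(bundles, pairs)
print(len(result.signature), "pairs selected")
for cohort, s in result.summary["wvg"].items():
    print(cohort, f"Wald p = {s['wald_p']:.2e}, accuracy = {s['accuracy']:.3f}")
print("common DEGs:", result.summary["n_deg_common"],
      "up in HR:", f"{100 * result.summary['deg_frac_up']:.0f}%")
```

prints

```
12 pairs selected
cohort1 Wald p = 5.12e-16, accuracy = 0.700
cohort2 Wald p = 6.36e-15, accuracy = 0.720
common DEGs: 84 up in HR: 75%
```

All 12 selected pairs are true signal pairs (`truth.signal_pair_ids()`);
the voted stratification separates the latent risk classes far more sharply
than any individual pair, and the common differentially expressed genes are
dominated by the up-in-high-risk direction, mirroring the behaviour the
method is designed to expose.

A command-line interface `sagp-risk` exposes the stages
(`simulate`, `screen`, `fit-pairs`, `stratify`, `deg`, `enrich`,
`cbr-overlap`, `cnv-compare`, `run`); see `sagp-risk --help`.

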