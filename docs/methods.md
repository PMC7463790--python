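# Methods

## Quantification model

Targets are quantified by the comparative-Ct method against the
endogenous control PPIA, chosen for its stability and high abundance in
cell-free saliva. Per (sample, target), technical replicate Ct values
are averaged over *detected* wells (Ct averaging, not relative-
expression averaging, is standard comparative-Ct practice and matches
triplicate ΔCt measurement); ΔCt is the target mean minus the
normalizer mean; relative expression is `2^(−ΔCt)` with the
amplification efficiency fixed at 2 — no efficiency calibration is
modelled. Undetected wells are encoded as missing values, never as a
sentinel cycle such as 40; a sample whose normalizer is entirely
undetected is unquantifiable and is dropped with a logged warning (or
raises on request).

The composite panel score sums *relative expression* over the seven
targets. Summing on the ΔCt scale is exposed as
`score_scale="delta_ct"` for sensitivity analyses; the relative-
expression sum is the default because the panel endpoint is a summed
abundance. No reference-sample baseline is subtracted: none is defined
for this panel. Missing-target policy: by default the composite score
requires all seven targets detected (strict); the alternative
(`missing_policy="rescale"`) rescales the sum of detected targets by
`7 / n_detected`. Dropout handling is a design choice of this package —
the assay itself defines no policy.

## Statistical tests

All permutation p-values use the plus-one estimator
`p = (b + 1) / (B + 1)`, which is never zero and is exactly valid under
exchangeability. A tiny relative tolerance (1e-12) is applied when
comparing permuted statistics to the observed one so that ties are
counted as at-least-as-extreme, making degenerate cases (identical
groups) return p = 1 exactly.

**Two-group comparison.** The endpoint (composite score or one target's
relative expression) is compared between healthy and patient groups
with a two-sided permutation test on the difference of group means.
The permutation null is assumption-light — relative-expression values
are right-skewed and not claimed normal — which is why it is the
default over a *t*-test; Welch's *t* (scipy) is available as
`method="welch"`. When the number of distinct label assignments
C(n, n₁) is at most 10⁴ the test enumerates all assignments and the
p-value is exact; tests verify the Monte-Carlo path against this
enumeration. Across the seven targets plus the composite, Holm-adjusted
p-values are reported alongside raw ones in one family; raw p-values
remain the primary report for comparability with single-endpoint use.

**Age stratification.** Samples are split at an age cut (young:
age < cut; old: age ≥ cut). The default cut is the pooled median age at
collection — no published cut exists, and the median keeps strata
balanced; `age_cut` overrides it. Samples without an age are excluded
with a log entry.

**Treatment sub-group permutation.** Within the patient cohort the
observed statistic is |mean(composite, sub-group) − mean(composite,
remainder)|; the null distribution draws B random sub-groups of the
same size uniformly without replacement (default B = 1000, the study's
count), switching to exhaustive enumeration when C(n, k) ≤ 10⁵. The
two-sided absolute-difference statistic on the composite score is a
reconstruction choice — the original analysis does not state sidedness
or endpoint — and a per-target option exists. Sub-groups are defined by
case-insensitive substring match on the free-text treatment field
(canonical labels: avastin, palbocyclib, hormonal, chemotherapy, her2,
afinitor); scanning all labels reports Holm-adjusted p-values alongside
raw ones because the label scan is a multiplicity-prone screen.

**Reproducibility.** Per-target CV = sample SD (n−1) / mean, computed on
the relative-expression scale by default (switchable to ΔCt). CV is
undefined (NaN, flagged) for n < 2 or non-positive mean. No hard
"reproducible" cut-off is enforced; a conventional CV ≤ 0.25 reading is
left to the user since no published threshold exists. The within- vs
between-subject comparison takes a repeat series (one woman, D days)
and a diversity series (W women, one day each) and computes the
variance ratio between/within; the one-sided reference distribution
shuffles the pooled values between the two series (permutation) because
normality is not assumed; a parametric F-test is an option. If both
series are one constant the ratio is undefined and p = 1 by policy.

**Variance components.** For a balanced subjects × days design the
method-of-moments estimator takes within = mean of per-subject sample
variances across days and between = variance of subject means −
within / D, clipped at zero. A mixed-model REML fit would add nothing at
these scales. When replicate noise is present, the day-level term
estimated from aggregated ΔCt values includes a `2σ_rep²/3`
contribution (triplicates enter both the target and normalizer means);
with the small default replicate SD this inflates the within-SD by
under 4%.

## Count filtering

Filters run in a fixed order — biotype exclusion, then total-count,
then presence — and each is idempotent. The excluded-biotype list is
the 19 non-informative classes (IG, TR, artifact, miRNA, Mt_rRNA,
Mt_tRNA, ncRNA, piRNA, pre-miRNA, rRNA, ribozyme, sRNA, scRNA, scaRNA,
siRNA, snRNA, snoRNA, tRNA, vaultRNA); genes with *missing* biotype are
retained with a warning, since exclusion is by listed class only. The
low-count filter removes genes with summed counts < 3 over all samples
(boundary: a row-sum of exactly 3 is retained). The presence call on
the pooled sample uses ≥ 49 reads, with the boundary read as inclusive
(49 is present); the convention is configurable because the published
threshold does not disambiguate ≥ from >. Presence is applied last,
after both filters. The abundance histogram uses half-open [lo, hi)
bins with below-range and overflow genes folded into the first/last
bin so the histogram mass always equals the gene count.

## Synthetic-data generators

**Ct tables.** For subject *i* (group x_i), day *d*, target *g*,
replicate *r*:

```
Ct_g − Ct_norm = mu_g + beta_g·1[x_i = patient] + u_{g,i} + e_{g,i,d} + ε_r
u ~ N(0, σ_between²),  e ~ N(0, σ_within²),  ε ~ N(0, σ_replicate²)
```

with the normalizer drawn around a fixed 24-cycle baseline with
replicate noise only (the control is treated as stable — no disease
effect). All effects are in cycles (1 cycle = 2-fold). Defaults encode
the study conditions: 36 healthy vs 31 patients, triplicates, ages
drawn per group from N(40, 12²) and N(53, 13²) years (clipped to
18–95), and disease-effect signs putting HNRNPA2B1 slightly down
(β = +0.4 cycles) and the other six targets up (β = −0.7 cycles) in
patients. The source study publishes no numeric variance components or
effect sizes, so the defaults are this package's calibration choices:
σ_between = 0.8, σ_within = 0.25, σ_replicate = 0.12 cycles, i.e. a
stable per-woman fingerprint dominating day-to-day drift, with effect
sizes set by power arithmetic so the 36-vs-31 composite comparison
rejects with high power at α = 0.05. One top-level seed drives
generation; per-stage and per-endpoint streams are split off it with
`SeedSequence.spawn` in a fixed order, so identical seeds give
bit-identical outputs.

**Count tables.** Gene-level means follow a Pareto law (tail index
0.55, scale 0.3 expected reads) with Poisson counts, giving the classic
long-tailed cell-free abundance profile: at the 20 000-gene default,
about 1250 genes exceed the 49-read presence cutoff before biotype
exclusion (the survival function `(1 + x/0.3)^(−0.55)` at x = 49 gives
≈ 6.1%), matching the scale of the pooled-library presence analysis the
filters were designed around; with the default 25% excluded-biotype
fraction, ≈ 930 genes are called present after filtering. The shape was
fixed from this closed form, not tuned to any test outcome.

**Metadata.** Synthetic records mirror the clinical-table schema (ages
with diagnosis ≤ collection, IDC/ILC flags, HER2 ±, metastasis-site
strings including "Local disease" and blanks, free-text treatments
drawn from the canonical label set) and round-trip through the parser.
They are labelled synthetic and share no values with the bundled real
table.

What the generators do **not** emulate: amplification-efficiency
drift, inter-plate batch effects, correlated dropout of low-abundance
targets, age–expression dependence, treatment effects on expression,
library-preparation biases, or exosome biology. Passing tests therefore
demonstrate the correctness and calibration of the *statistics* under
the assumed hierarchical Gaussian-on-Ct model, not clinical performance
on real saliva.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study's cohort sizes
(36/31) for cohort-level checks; null calibration uses 500 simulated
cohorts with 199 permutations each (p-values on a 1/200 grid keep the
α = 0.05 rejection rule exact); variance-component recovery uses 200
subjects × 5 days with replicate noise off so the estimator targets the
generator's parameters directly; reproducibility designs use 10 days ×
1 woman vs 10 women × 1 day, the study's design. Exhaustive-enumeration
limits (10⁴ label assignments, 10⁵ sub-groups) keep exact tests under a
second.

## Known limitations

- The package reproduces the *workflow*, not the original measurements:
  the study's saliva qPCR data are not public, so its headline p-values
  are not recomputable and are not targets of this package.
- The strict missing-target policy discards samples with any panel
  dropout; the rescaled score changes the estimand and should be
  reported as such.
- The variance-component estimator assumes a balanced design and
  errors otherwise.
- Treatment matching is substring-based on free text; misspelled
  treatment entries (e.g. "navalbine") match only themselves.
- The clinical table transcribes its source faithfully, including a row
  flagged with both IDC and ILC histology; consumers should treat the
  histology flags as recorded, not validated.
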