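# Methods

## The analysis this package implements

The pipeline analyzes label-free spectral-count proteomes from a pooled 2×2
factorial design: two genotypes (intact control vs. intestinal-epithelial
IGF-1-receptor knockout) crossed with two treatments (vehicle vs. a
long-acting GLP-2 receptor agonist). Each group is a **single pooled
sample** (whole small intestines from many animals combined before brush
border membrane isolation), so each protein contributes exactly four
numbers — one spectral count per group, in the fixed order
`ctrl_vehicle, ctrl_glp2, ko_vehicle, ko_glp2`.

The analysis proceeds in four stages:

1. **Annotation-based focusing.** Term enrichment over the identified
   proteome selects a structurally relevant protein subset (for brush
   border work, an actin-filament–type cellular-component term). We test
   each term with a one-sided hypergeometric tail P[X ≥ k] on the
   identified-proteome universe and control the family with
   Benjamini–Hochberg. Terms with zero query overlap are untestable and are
   excluded from both the output and the BH family (they would only
   inflate the family size m).
2. **Max-normalization.** Each protein's four counts are divided by their
   maximum, then floored at 0.01, yielding a profile in [0.01, 1] whose
   largest entry is exactly 1. The floor is what makes a zero count
   representable after division (0 → 0.01); it is exposed as a setting.
3. **Template Pearson classification.** The profile is correlated against
   idealized four-value templates built from a 0.5 baseline and a 0.3
   change step:
   - `cat1` (treatment effect requiring the intact receptor):
     (0.5, 0.8, 0.5, 0.5);
   - `cat2` (effect of receptor loss alone): (0.5, 0.5, 0.8, 0.8);
   - mirrored `-down` variants subtract the step.
   Pearson correlation is invariant to affine rescaling of the template, so
   only the *pattern* matters — any other step magnitude yields identical
   r. The p-value uses the exact t transform t = r·sqrt(df/(1−r²)) with
   df = n − 2 = 2 (four observations), two-sided. A category is called only
   when (i) the best template's p < α = 0.05, (ii) every group the template
   marks as changed deviates from the **mean of the unchanged groups** by at
   least 0.3 in the template's direction, and (iii) the unchanged groups
   agree pairwise within 0.1. Profiles whose four values all agree within
   0.1 are `null`; everything else is `unclassified`.
4. **Supporting factorial statistics** for per-mouse follow-up data:
   fixed-effects 2×2 ANOVA with Sidak-adjusted cell-wise post-hoc
   comparisons, 2^−ΔΔCT relative quantification for qPCR, and densitometry
   normalization to the vehicle-treated control group through a paired
   loading control.

## Design choices where the procedure was genuinely open

**Template candidacy and tie-breaking.** The up- and down-variants of one
family are exactly anticorrelated vectors, so they always tie on R². A
template is therefore a *candidate* only when its correlation is positive
(a profile matching the down pattern correlates positively with the down
template). A residual R² tie **across families** (cat1 vs. cat2) is a
genuine ambiguity between biological interpretations; it is reported as
`unclassified` with a `tie` flag rather than resolved by a guess.

**"Compared to other groups."** The change rule measures each changed
group's deviation from the mean of the template's unchanged groups: those
groups jointly estimate the profile's baseline.

**Correlation on n = 4.** The correlation is computed on the four pooled
group values (df = 2), matching the pooled design. At df = 2 the two-sided
5% critical value is |r| ≈ 0.950, i.e. R² ≈ 0.902 — category-grade calls
require near-perfect pattern agreement, and the p-value is fragile; the
pipeline logs this caveat at the start of every run.

**Threshold comparisons** are inclusive up to a 1e−9 float tolerance
(0.55 − 0.45 must count as "within 0.1"). Perfect correlations report the
p-value at the smallest positive double rather than 0, keeping p in (0, 1].

**ANOVA sums of squares.** Unbalanced designs (per-mouse group sizes in
follow-up experiments commonly range n = 7–15) use type-II SS: the 2×2 design implies no factor ordering. On
balanced data type II coincides with the textbook decomposition, and the
suite asserts SS conservation to 1e−10 relative tolerance.

**ΔΔCT.** Amplification efficiency is fixed at 2 (classic ΔΔCT); no
efficiency correction.

## The synthetic-data generator

`generate_proteome` draws integer counts from a gamma-Poisson (negative
binomial) law with variance μ + φμ², one column per group — the pooled
design has no replicate columns, and φ (the `dispersion`) absorbs
biological plus technical noise, whose true magnitude a pooled design
cannot reveal. Planted `cat1` proteins have a multiplicative effect applied
to `ctrl_glp2` only; `cat2` proteins to both knockout groups; everything
else shares a flat expectation (`baseline_mean`). A configurable fraction
of planted proteins is down-regulated (effect 1/fold); the default is 0,
reflecting that the motivating biology concerns increases. The annotation
generator plants one focal term covering planted proteins at rate
`enriched_term_fraction` (default 0.9) against 20 uniform background terms
at 5% coverage. Morphometry defaults emulate microvillus lengths: control
1.0 µm, a 1.3-fold treatment effect in controls only, shorter (0.8 µm)
knockouts with no treatment response, 10% CV, five mice per group. The CT
generator lowers the target CT by log2(fold) cycles with the reference gene
unchanged, so 2^−ΔΔCT recovers the planted fold in expectation.

Defaults: `n_proteins=1000`, `baseline_mean=50`, `dispersion=0.05`,
`effect_size=3`, 5% planted per category — a realistic mid-abundance
pooled proteome.

What the generator does **not** emulate: peptide-level evidence and
protein-inference ambiguity, missingness beyond structural zeros, batch or
run-order effects, and correlated abundances between interacting proteins.
Passing recovery tests therefore demonstrate the *procedure's* operating
characteristics under its own noise model, not performance guarantees on
real membrane proteomes.

## Benchmark conditions and problem sizes

Two named conditions recur in the tests and the acceptance script:

- **Low-noise recovery benchmark**: n = 1000 proteins, 5% + 5% planted,
  3-fold effects, `baseline_mean=500`, `dispersion=0.001`. Counting noise
  alone imposes a relative-error floor of 1/√μ, so "low noise" requires
  high counts as well as low overdispersion — at μ = 50 the ~14% CV makes
  the pairwise no-change rule fail by sampling noise alone regardless of φ.
  μ = 500 describes the abundant structural proteins the classification
  targets. Under this condition the classifier recovers ≥ 90% (in practice
  all) of planted categories with ≤ 5% (in practice zero) null miscalls.
- **Null/type-I condition**: the generator defaults with no planted
  proteins, 20 seeds. The non-null call fraction sits near 3%, and the
  regression band frozen in the suite (mean in [0.01, 0.05], each seed in
  [0.005, 0.06]) guards against silent drift of the rule's false-call rate.

Simulation sizes throughout (1000 proteins, 20 seeds, 50 replicate
morphometry experiments, 20 qPCR plates) were chosen so every stage's
sampling error is small relative to the quantities reported while the whole
suite runs in seconds.

## Known limitations

- With a single pooled sample per group there is no within-group replication:
  the Pearson p at df = 2 is a pattern-agreement score, not a substitute for
  replicate-aware inference, and no shrinkage or moderated statistics are
  attempted.
- The annotation model is a flat term → gene map; no ontology-graph
  propagation (is-a/part-of closure) is performed.
- Fold changes on pooled counts carry no uncertainty estimate; they are
  descriptive ratios.
- The enrichment query in the end-to-end pipeline is a simple spread-based
  pre-screen (profile range ≥ change threshold); it is deliberately cheap
  and is not itself a calibrated test.
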