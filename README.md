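# bbmprofiler

Pattern analysis for pooled 2×2 factorial spectral-count proteomes — built
for brush-border-membrane (BBM) studies asking which structural proteins
respond to a treatment through a given receptor, and which respond to loss
of the receptor itself.

## The problem

Intestinal microvilli are maintained by a small set of structural proteins
(villin, IRTKS-1, harmonin, β-actin, myosin-1a, …). In a 2×2 design —
genotype (control vs. intestinal-epithelial IGF-1-receptor knockout) ×
treatment (vehicle vs. a long-acting GLP-2 analog) — membrane proteomes are
measured as **one pooled sample per group**, so each protein is just four
spectral counts. The question per protein: does its pattern across
(control-vehicle, control-treated, KO-vehicle, KO-treated) look like

- **category 1** — a treatment effect that requires the intact receptor
  (only the treated control group deviates), or
- **category 2** — an effect of receptor loss alone (both KO groups
  deviate)?

## The method

For each protein with counts c = (c₁…c₄), the normalized profile is
vᵢ = max(cᵢ / max c, 0.01) ∈ [0.01, 1]. Each profile is scored against
template vectors built from baseline b = 0.5 and change step Δ = 0.3:

    cat1-up = (0.5, 0.8, 0.5, 0.5)    cat2-up = (0.5, 0.5, 0.8, 0.8)

(plus mirrored down-variants) using the Pearson correlation r, with
p from t = r·√(df/(1−r²)), df = n−2 = 2, two-sided. A category is called
iff p < 0.05 **and** the changed group(s) deviate ≥ 0.3 from the mean of
the unchanged groups **and** the unchanged groups agree pairwise ≤ 0.1;
profiles whose four values all agree within 0.1 are `null`, the rest
`unclassified`. At df = 2 a call needs |r| ≥ 0.950 (R² ≥ 0.90).

Around this core the package provides hypergeometric term enrichment with
Benjamini–Hochberg control (to focus on, e.g., actin-filament proteins),
group fold changes, a planted-truth synthetic-data generator, and the
supporting per-mouse statistics (2×2 ANOVA + Sidak post-hoc, 2^−ΔΔCT,
loading-control densitometry normalization). See `docs/methods.md`.

The classifier is an sklearn-style estimator and composes with sklearn
pipelines:

```python
from bbmprofiler import TemplatePatternClassifier
clf = TemplatePatternClassifier().fit()
clf.predict([[500, 1500, 500, 500]])   # -> array(['cat1-up'], ...)
```

## Worked example

Simulate a 1000-protein proteome with 5% planted category-1 and 5%
category-2 proteins (3-fold effects, low-noise counts), then run the full
pipeline:

```python
from bbmprofiler import SimulationConfig
from bbmprofiler.pipeline import PipelineConfig, run_pipeline

sim = SimulationConfig(n_proteins=1000, frac_cat1=0.05, frac_cat2=0.05,
                       effect_size=3.0, dispersion=1e-3, baseline_mean=500.0)
manifest = run_pipeline(PipelineConfig(out_dir="run", seed=11, simulation=sim))
```

The manifest (also written to `run/manifest.yaml`) reports per stage:

```
enrich:
  query_genes: 100            # proteins passing the differential pre-screen
  terms_significant: 1        # the planted focal term, BH-adjusted p < 0.05
  subset_proteins: 137        # proteins annotated to it
classify:
  proteins_in: 137
  calls: {cat2-up: 49, cat1-up: 46, null: 22, unclassified: 20}
```

`run/classification.tsv` holds one row per protein, e.g. a recovered
category-1 protein:

```
protein_id category        r       r2        p  fold_glp2_ctrl
     P0015  cat1-up 0.999128 0.998257 0.000872        2.911824
```

— its profile correlates with the cat1-up template at R² = 0.998
(p < 0.05 at df = 2), and its treated-control/vehicle-control fold change
(2.91) recovers the planted 3-fold effect. All 95 planted proteins inside
the subset are called in their true category here; the 22 `null` and 20
`unclassified` rows are background proteins the focal term also covers.

The same stages are available from the shell:

```
bbmprofiler simulate --n-proteins 1000 --seed 11 \
    --counts-out counts.tsv --truth-out truth.tsv --annotation-out ann.tsv
bbmprofiler enrich --counts counts.tsv --annotation ann.tsv --out enrich.tsv
bbmprofiler classify --counts counts.tsv --out calls.tsv
bbmprofiler run --config pipeline.yaml
```

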