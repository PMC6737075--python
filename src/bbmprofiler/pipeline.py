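"""Orchestrate simulate -> enrich -> classify -> stats as one reproducible run.

A run is driven by a :class:`PipelineConfig` (loadable from YAML), writes
TSV artifacts plus a YAML manifest into the output directory, and is fully
determined by its global seed.  The global seed is fanned out to per-stage
seeds by fixed offsets so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import enrich_terms, enrichment_frame, select_term_proteins
from .factorial_stats import ddct_fold, two_way_anova
from .pattern import ClassifierSettings, classify_table
from .simulate import (
    FOCAL_TERM,
    MorphometryConfig,
    SimulationConfig,
    generate_annotation,
    generate_ct_table,
    generate_morphometry,
    generate_proteome,
)
from .tables import (
    read_annotation,
    read_count_table,
    write_annotation,
    write_count_table,
    write_ct_table,
    write_enrichment,
    write_measurements,
    write_results,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage-level reproducibility)
SEED_OFFSETS = {"proteome": 0, "morphometry": 101, "ct": 202}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def differential_query(table, settings: ClassifierSettings) -> list[str]:
    """Genes showing a provisional differential signal.

    A cheap pre-screen feeding the enrichment query: a protein is a
    candidate when its normalized profile spans at least the change
    threshold (some group deviates that far from some other).  Mirrors
    assessing differentially expressed proteins for term enrichment before
    the template classification proper.
    """
    counts = table.counts()
    nz = counts.max(axis=1) > 0
    profiles = counts[nz] / counts[nz].max(axis=1, keepdims=True)
    spread = profiles.max(axis=1) - profiles.min(axis=1)
    return table.gene_symbols[nz][spread >= settings.change_threshold].tolist()


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (or simulation configs), settings, seed."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    counts_path: str | None = None       # load instead of simulating
    annotation_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    enrichment_alpha: float = 0.05
    focal_term: str | None = None        # default: best enriched term
    ct_true_folds: dict[str, float] = field(default_factory=lambda: {"treated": 2.0})
    ct_n_samples: int = 8
    ct_noise_sd: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (
            ("simulation", SimulationConfig),
            ("morphometry", MorphometryConfig),
            ("classifier", ClassifierSettings),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        for p in (self.counts_path, self.annotation_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: referenced path does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full run; returns the manifest dict (also written as YAML).

    Stage order mirrors the analysis: proteome -> ontology enrichment and
    subset -> pattern classification -> supporting factorial stats.  Any
    stage failure aborts with a stage-named error; the manifest marks the
    run incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = config.classifier
    logger.info(
        "settings: floor=%g baseline=%g change>=%g nochange<=%g alpha=%g "
        "(Pearson on n=4 pooled groups, df=2 — p-values at n=4 are fragile)",
        s.floor, s.baseline, s.change_threshold, s.nochange_threshold, s.alpha,
    )
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "complete": False,
        "config": _as_plain(config),
        "stages": {},
    }
    provenance = [f"bbmprofiler {__version__}", f"seed {config.seed}"]

    try:
        stage = "simulate"
        sim = dataclasses.replace(
            config.simulation, seed=config.seed + SEED_OFFSETS["proteome"]
        )
        if config.counts_path:
            table = read_count_table(config.counts_path)
            truth = None
        else:
            table, truth = generate_proteome(sim)
            write_count_table(table, out / "counts.tsv", provenance)
            write_results(truth.data, out / "planted_truth.tsv", provenance)
        if config.annotation_path:
            annotation = read_annotation(config.annotation_path)
        else:
            if truth is None:
                raise PipelineError("simulate: annotation_path required with counts_path")
            annotation = generate_annotation(truth, sim)
            write_annotation(annotation, out / "annotation.tsv", provenance)
        manifest["stages"][stage] = {"proteins": table.n_proteins, "terms": len(annotation)}

        stage = "enrich"
        universe = table.gene_symbols.tolist()
        query = differential_query(table, config.classifier)
        results = enrich_terms(query, annotation, universe)
        frame = enrichment_frame(results)
        write_enrichment(frame, out / "enrichment.tsv", provenance)
        if len(frame):
            significant = frame[frame["adjusted_p"] < config.enrichment_alpha]
        else:
            significant = frame
        focal = config.focal_term
        if focal is None and len(significant):
            focal = significant.iloc[0]["term"]
        if focal is None and FOCAL_TERM in annotation:
            focal = FOCAL_TERM
        if focal is None:
            raise PipelineError("enrich: no term available for subset selection")
        subset = select_term_proteins(focal, annotation, table)
        manifest["stages"][stage] = {
            "query_genes": len(query),
            "terms_tested": int(len(frame)),
            "terms_significant": int(len(significant)),
            "focal_term": focal,
            "subset_proteins": subset.n_proteins,
        }

        stage = "classify"
        target = subset if subset.n_proteins else table
        result, excluded = classify_table(target, config.classifier)
        write_results(result, out / "classification.tsv", provenance)
        counts_in = target.n_proteins
        assert counts_in == len(result) + len(excluded), "row accounting violated"
        manifest["stages"][stage] = {
            "proteins_in": counts_in,
            "proteins_classified": len(result),
            "proteins_excluded": len(excluded),
            "calls": {k: int(v) for k, v in result["category"].value_counts().items()},
        }

        stage = "stats"
        morph = dataclasses.replace(
            config.morphometry, seed=config.seed + SEED_OFFSETS["morphometry"]
        )
        measurements = generate_morphometry(morph)
        write_measurements(measurements, out / "morphometry.tsv", provenance)
        anova = two_way_anova(measurements)
        write_results(anova.table.reset_index(names="effect"), out / "anova.tsv", provenance)
        write_results(anova.posthoc, out / "anova_posthoc.tsv", provenance)
        ct = generate_ct_table(
            config.ct_n_samples,
            config.ct_true_folds,
            seed=config.seed + SEED_OFFSETS["ct"],
            noise_sd=config.ct_noise_sd,
        )
        write_ct_table(ct, out / "ct.tsv", provenance)
        per_sample, per_group = ddct_fold(ct, control_group="control")
        write_results(per_group, out / "ddct.tsv", provenance)
        manifest["stages"][stage] = {
            "anova_p_treatment": float(anova.p_treatment),
            "anova_p_interaction": float(anova.p_interaction),
            "ddct_groups": int(len(per_group)),
        }
        manifest["complete"] = True
    except PipelineError:
        _write_manifest(manifest, out)
        raise
    except Exception as exc:  # annotate with the failing stage
        _write_manifest(manifest, out)
        raise PipelineError(f"{stage}: {exc}") from exc

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
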