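"""Synthetic data with planted ground truth for every pipeline stage.

The proteome generator emulates a pooled 2x2 factorial label-free
spectral-count experiment: one column per group (each group is a single
pooled sample, as when whole small intestines from many animals are combined
before membrane isolation), overdispersed integer counts, and a minority of
proteins carrying one of two planted regulation patterns:

* ``cat1`` — treatment effect requiring the intact receptor: the effect is
  applied to the treated control group only (``ctrl_glp2``).
* ``cat2`` — effect of receptor loss alone: the effect is applied to both
  knockout groups (``ko_vehicle`` and ``ko_glp2``).

Counts are gamma-Poisson (negative binomial) with variance
``mu + dispersion * mu**2``, so ``dispersion -> 0`` recovers Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import GROUP_ORDER
from .tables import (
    AnnotationMap,
    CtTable,
    MeasurementTable,
    SpectralCountTable,
)


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth proteome simulator.

    Defaults describe a realistic pooled spectral-count study: ~1000
    detectable proteins, a baseline expectation of 50 spectra per protein
    per pooled sample, 3-fold planted effects, and mild biological+technical
    overdispersion.
    """

    n_proteins: int = 1000
    frac_cat1: float = 0.05
    frac_cat2: float = 0.05
    frac_down: float = 0.0  # fraction of planted proteins regulated downward
    effect_size: float = 3.0
    dispersion: float = 0.05
    baseline_mean: float = 50.0
    enriched_term_fraction: float = 0.9
    n_background_terms: int = 20
    background_coverage: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be a positive integer")
        for name in ("frac_cat1", "frac_cat2", "frac_down", "enriched_term_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_cat1 + self.frac_cat2 > 1.0:
            raise ConfigurationError("frac_cat1 + frac_cat2 must be <= 1")
        if self.effect_size <= 1.0:
            raise ConfigurationError("effect_size must exceed 1")
        for name in ("dispersion", "baseline_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass
class PlantedTruth:
    """Ground-truth labels emitted alongside a simulated proteome.

    ``data`` has one row per protein: ``protein_id``, ``gene_symbol``,
    ``label`` (null | cat1 | cat2), ``direction`` (up | down), ``effect``
    (realized multiplicative fold), ``focal_term`` (bool membership in the
    enriched annotation term).
    """

    data: pd.DataFrame

    def labels(self) -> pd.Series:
        return self.data.set_index("protein_id")["label"]

    def planted_ids(self) -> list[str]:
        return self.data.loc[self.data["label"] != "null", "protein_id"].tolist()


FOCAL_TERM = "planted_focal_term"


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # gamma-Poisson: shape r = 1/dispersion, p = r / (r + mu)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_proteome(config: SimulationConfig) -> tuple[SpectralCountTable, PlantedTruth]:
    """Simulate a four-group pooled spectral-count table with planted patterns.

    Returns the count table and a :class:`PlantedTruth` labeling every row
    exactly once.  cat1 proteins have the effect applied to ``ctrl_glp2``
    only; cat2 proteins to both knockout groups; null proteins share a common
    expected count across all groups.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_cat1 = int(round(config.frac_cat1 * n))
    n_cat2 = int(round(config.frac_cat2 * n))

    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_cat1]] = "cat1"
    labels[order[n_cat1 : n_cat1 + n_cat2]] = "cat2"

    planted = labels != "null"
    directions = np.array(["up"] * n, dtype=object)
    if config.frac_down > 0:
        down = rng.random(n) < config.frac_down
        directions[planted & down] = "down"

    effects = np.ones(n)
    effects[planted & (directions == "up")] = config.effect_size
    effects[planted & (directions == "down")] = 1.0 / config.effect_size

    mu = np.full((n, 4), config.baseline_mean, dtype=float)
    cat1 = labels == "cat1"
    cat2 = labels == "cat2"
    mu[cat1, 1] *= effects[cat1]          # ctrl_glp2 only
    mu[cat2, 2] *= effects[cat2]          # ko_vehicle
    mu[cat2, 3] *= effects[cat2]          # ko_glp2

    counts = _nb_draw(rng, mu, config.dispersion)

    width = len(str(n))
    ids = [f"P{i:0{width}d}" for i in range(n)]
    symbols = [f"Gene{i:0{width}d}" for i in range(n)]
    table = SpectralCountTable(
        pd.DataFrame(
            {
                "protein_id": ids,
                "gene_symbol": symbols,
                **{g: counts[:, j] for j, g in enumerate(GROUP_ORDER)},
            }
        )
    )
    truth = PlantedTruth(
        pd.DataFrame(
            {
                "protein_id": ids,
                "gene_symbol": symbols,
                "label": labels,
                "direction": np.where(planted, directions, "up"),
                "effect": effects,
                "focal_term": False,
            }
        )
    )
    return table, truth


def generate_annotation(
    truth: PlantedTruth,
    config: SimulationConfig,
    include_focal: bool = True,
) -> AnnotationMap:
    """Emit a term->gene map with one focal term covering planted proteins.

    The focal term includes each planted protein with probability
    ``enriched_term_fraction`` plus background genes at the background
    coverage rate; additional background terms cover genes uniformly.  The
    truth object's ``focal_term`` column is updated in place so downstream
    recovery checks can see actual membership.
    """
    if truth.data.empty:
        raise ConfigurationError("cannot annotate an empty truth table")
    # seed offset keeps the annotation reproducible yet decoupled from counts
    rng = np.random.default_rng(config.seed + 1)
    genes = truth.data["gene_symbol"].to_numpy()
    planted = (truth.data["label"] != "null").to_numpy()

    terms: dict[str, frozenset] = {}
    if include_focal:
        in_focal = planted & (rng.random(len(genes)) < config.enriched_term_fraction)
        # pad with background genes so the term is not purely planted
        background = ~planted & (rng.random(len(genes)) < config.background_coverage)
        members = genes[in_focal | background]
        if len(members) == 0:
            members = genes[:1]
            in_focal = np.zeros(len(genes), dtype=bool)
        truth.data["focal_term"] = in_focal | background
        terms[FOCAL_TERM] = frozenset(members)
    for b in range(config.n_background_terms):
        cover = rng.random(len(genes)) < config.background_coverage
        if not cover.any():
            cover[rng.integers(len(genes))] = True
        terms[f"background_term_{b:02d}"] = frozenset(genes[cover])
    return AnnotationMap(terms)


@dataclass
class MorphometryConfig:
    """Per-group normal model for a continuous per-mouse measurement.

    Defaults emulate microvillus length (um): a 1.3-fold treatment effect in
    control animals, shorter microvilli in knockouts with no treatment
    response, 10% coefficient of variation, five mice per group.
    """

    group_means: dict[str, float] = field(
        default_factory=lambda: {
            "ctrl_vehicle": 1.0,
            "ctrl_glp2": 1.3,
            "ko_vehicle": 0.8,
            "ko_glp2": 0.8,
        }
    )
    group_sds: dict[str, float] = field(
        default_factory=lambda: {g: 0.1 for g in GROUP_ORDER}
    )
    n_mice: int = 5
    unit: str = "um"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ConfigurationError("n_mice must be >= 2 per group (ANOVA estimability)")
        missing = [g for g in GROUP_ORDER if g not in self.group_means]
        if missing:
            raise ConfigurationError(f"group_means missing groups: {missing}")
        if any(self.group_sds.get(g, 0.0) < 0 for g in GROUP_ORDER):
            raise ConfigurationError("group SDs must be >= 0")


def generate_morphometry(config: MorphometryConfig) -> MeasurementTable:
    """Simulate a balanced per-mouse measurement table (one row per mouse)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in GROUP_ORDER:
        geno, trt = group.split("_", 1)
        mean = config.group_means[group]
        sd = config.group_sds.get(group, 0.0)
        values = rng.normal(mean, sd, size=config.n_mice) if sd > 0 else np.full(config.n_mice, mean)
        for i, v in enumerate(values):
            rows.append(
                {
                    "mouse_id": f"{group}_m{i:02d}",
                    "genotype": geno,
                    "treatment": trt,
                    "value": v,
                }
            )
    return MeasurementTable(pd.DataFrame(rows), unit=config.unit)


def generate_ct_table(
    n_samples: int,
    true_folds: dict[str, float],
    seed: int = 0,
    control_group: str = "control",
    noise_sd: float = 0.0,
    reference_ct: float = 20.0,
    target_baseline_ct: float = 25.0,
) -> CtTable:
    """Simulate qPCR CT values whose 2^-ddCT recovers ``true_folds`` in expectation.

    Under efficiency-2 amplification a fold change f lowers the target CT by
    log2(f) cycles relative to the control group, with the reference gene
    unchanged.  ``true_folds`` maps group label -> fold relative to
    ``control_group`` (which is implicitly fold 1 and need not be listed).
    """
    folds = dict(true_folds)
    folds.setdefault(control_group, 1.0)
    if any(f <= 0 for f in folds.values()):
        raise ConfigurationError("true folds must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in folds.items():
        for i in range(n_samples):
            noise_t = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            noise_r = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": f"{group}_s{i:02d}",
                    "group": group,
                    "ct_target": target_baseline_ct - np.log2(fold) + noise_t,
                    "ct_reference": reference_ct + noise_r,
                }
            )
    return CtTable(pd.DataFrame(rows))
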