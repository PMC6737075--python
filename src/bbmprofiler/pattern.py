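"""Template-correlation classification of four-group expression patterns.

The core procedure: each protein's four pooled-group spectral counts are
normalized to their maximum (floored at 0.01 so zeros stay representable),
then correlated (Pearson) against idealized template vectors built on a 0.5
baseline with a +/-0.3 change step:

* ``cat1`` — treatment effect requiring the intact receptor: only the
  treated control group deviates, template (0.5, 0.8, 0.5, 0.5).
* ``cat2`` — effect of receptor loss alone: both knockout groups deviate,
  template (0.5, 0.5, 0.8, 0.8).

Down-regulated variants mirror the step below baseline.  A category is
called only when the best-matching template is significantly correlated
(two-sided t test on r with df = n - 2 = 2) AND the explicit threshold rules
hold: every "changed" group deviates from the mean of the unchanged groups
by at least 0.3 in the template's direction, and the unchanged groups agree
pairwise within 0.1.  Profiles whose groups all agree within 0.1 are "null";
everything else is "unclassified".

Because Pearson correlation is invariant to affine rescaling of the
template, only the PATTERN of the template matters — any other step
magnitude gives identical r.  The up- and down-variants of one family are
exactly anticorrelated (identical R^2 always); a template is therefore a
candidate only when its correlation is positive, and the R^2 tie that
matters — between the two biological families — yields "unclassified" with
a tie flag rather than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .groups import GROUP_ORDER, N_GROUPS
from .tables import SpectralCountTable

__all__ = [
    "ClassifierSettings",
    "TemplateModel",
    "ProfileNormalizer",
    "TemplatePatternClassifier",
    "normalize_profile",
    "build_templates",
    "correlate",
    "classify",
    "classify_table",
    "fold_change",
]

_DF = N_GROUPS - 2  # residual df of a Pearson correlation on four values
_P_FLOOR = np.finfo(float).tiny  # p is reported in (0, 1]; |r| = 1 hits the floor
_TIE_TOL = 1e-12
_EPS = 1e-9  # threshold comparisons are inclusive up to float rounding

CATEGORIES = ("cat1-up", "cat1-down", "cat2-up", "cat2-down")


@dataclass(frozen=True)
class ClassifierSettings:
    """Printed constants of the classification rule.

    baseline 0.5 and change step 0.3 define the templates; a deviation
    >= 0.3 from the unchanged groups counts as a change, pairwise agreement
    <= 0.1 counts as no change; normalized values are floored at 0.01.
    """

    baseline: float = 0.5
    change_threshold: float = 0.3
    nochange_threshold: float = 0.1
    floor: float = 0.01
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.nochange_threshold < self.change_threshold:
            raise ValueError(
                "need 0 < nochange_threshold < change_threshold, got "
                f"{self.nochange_threshold} / {self.change_threshold}"
            )
        if self.baseline + self.change_threshold > 1.0:
            raise ValueError("baseline + change_threshold must not exceed 1")
        if not 0 < self.floor < 1:
            raise ValueError("floor must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class TemplateModel:
    """A named ideal four-value pattern in canonical group order."""

    category: str
    values: tuple[float, float, float, float]
    changed: tuple[int, ...]  # indices of groups the template marks as changed
    direction: int  # +1 up, -1 down

    def __post_init__(self) -> None:
        if np.std(self.values) == 0:
            raise ValueError(f"template {self.category!r} has zero variance")


def build_templates(settings: ClassifierSettings | None = None) -> list[TemplateModel]:
    """Build the four differential-expression templates in fixed order."""
    s = settings or ClassifierSettings()
    b, c = s.baseline, s.change_threshold
    return [
        TemplateModel("cat1-up", (b, b + c, b, b), changed=(1,), direction=+1),
        TemplateModel("cat1-down", (b, b - c, b, b), changed=(1,), direction=-1),
        TemplateModel("cat2-up", (b, b, b + c, b + c), changed=(2, 3), direction=+1),
        TemplateModel("cat2-down", (b, b, b - c, b - c), changed=(2, 3), direction=-1),
    ]


def normalize_profile(counts, settings: ClassifierSettings | None = None) -> np.ndarray:
    """Normalize four counts to their maximum, flooring at ``settings.floor``.

    Raises ``ValueError`` for an all-zero quadruple (callers operating on
    whole tables exclude such proteins with a logged reason instead).
    """
    s = settings or ClassifierSettings()
    v = np.asarray(counts, dtype=float)
    if v.shape != (N_GROUPS,):
        raise ValueError(f"expected {N_GROUPS} counts, got shape {v.shape}")
    if (v < 0).any():
        raise ValueError("counts must be non-negative")
    m = v.max()
    if m == 0:
        raise ValueError("all counts are zero; profile undefined")
    return np.maximum(v / m, s.floor)


def correlate(profile, template) -> tuple[float, float, float]:
    """Pearson r, R^2 and two-sided p of a profile against a template.

    p comes from t = r * sqrt(df / (1 - r^2)) with df = 2; |r| = 1 returns p
    at the numeric floor rather than erroring.  A zero-variance profile has
    no defined correlation: returns (nan, nan, nan).
    """
    x = np.asarray(profile, dtype=float)
    t = np.asarray(template.values if isinstance(template, TemplateModel) else template, dtype=float)
    if x.shape != (N_GROUPS,) or t.shape != (N_GROUPS,):
        raise ValueError("profile and template must both have four values")
    if np.std(t) == 0:
        raise ValueError("template has zero variance; correlation undefined")
    if np.std(x) == 0:
        return (float("nan"), float("nan"), float("nan"))
    r = float(np.corrcoef(x, t)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    r2 = r * r
    if r2 >= 1.0:
        return (r, 1.0, _P_FLOOR)
    tstat = abs(r) * np.sqrt(_DF / (1.0 - r2))
    p = float(max(2.0 * stats.t.sf(tstat, _DF), _P_FLOOR))
    return (r, r2, p)


class ProfileNormalizer(TransformerMixin, BaseEstimator):
    """Row-wise max normalization with a representability floor.

    Transforms an (n, 4) count matrix so every row's maximum is exactly 1
    and no entry falls below ``floor``.  Rows that are entirely zero have no
    defined profile and raise; table-level drivers filter them out first.
    """

    def __init__(self, floor: float = 0.01):
        self.floor = floor

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=N_GROUPS)
        if X.shape[1] != N_GROUPS:
            raise ValueError(f"expected {N_GROUPS} group columns, got {X.shape[1]}")
        if not 0 < self.floor < 1:
            raise ValueError("floor must lie in (0, 1)")
        self.n_features_in_ = N_GROUPS
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_min_features=N_GROUPS)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        m = X.max(axis=1)
        if (m == 0).any():
            bad = np.flatnonzero(m == 0)
            raise ValueError(f"all-zero rows have no profile: indices {bad.tolist()}")
        return np.maximum(X / m[:, None], self.floor)


class TemplatePatternClassifier(BaseEstimator):
    """Classify four-group count rows into regulation categories.

    A rule-based classifier: ``fit`` validates the settings and freezes the
    template set; ``predict`` maps an (n, 4) matrix of raw counts (or
    already-normalized profiles) to category strings among ``cat1-up``,
    ``cat1-down``, ``cat2-up``, ``cat2-down``, ``null`` and ``unclassified``.
    ``predict_detail`` returns the full per-row evidence (r, R^2, p, flags,
    fold changes).

    Parameters mirror :class:`ClassifierSettings`; ``normalize=False``
    accepts pre-normalized profiles.
    """

    def __init__(
        self,
        baseline: float = 0.5,
        change_threshold: float = 0.3,
        nochange_threshold: float = 0.1,
        floor: float = 0.01,
        alpha: float = 0.05,
        normalize: bool = True,
    ):
        self.baseline = baseline
        self.change_threshold = change_threshold
        self.nochange_threshold = nochange_threshold
        self.floor = floor
        self.alpha = alpha
        self.normalize = normalize

    def _settings(self) -> ClassifierSettings:
        return ClassifierSettings(
            baseline=self.baseline,
            change_threshold=self.change_threshold,
            nochange_threshold=self.nochange_threshold,
            floor=self.floor,
            alpha=self.alpha,
        )

    def fit(self, X=None, y=None):
        settings = self._settings()  # raises on invalid parameters
        self.settings_ = settings
        self.templates_ = build_templates(settings)
        self.classes_ = np.array([*CATEGORIES, "null", "unclassified"], dtype=object)
        self.n_features_in_ = N_GROUPS
        if X is not None:
            check_array(X, ensure_min_features=N_GROUPS)
        return self

    def _profiles(self, X) -> np.ndarray:
        X = check_array(X, ensure_min_features=N_GROUPS)
        if X.shape[1] != N_GROUPS:
            raise ValueError(f"expected {N_GROUPS} group columns, got {X.shape[1]}")
        if self.normalize:
            return ProfileNormalizer(self.settings_.floor).fit(X).transform(X)
        return X

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "templates_")
        return self.predict_detail(X)["category"].to_numpy()

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-row classification evidence.

        Columns: category, template, r, r2, p, change_ok, nochange_ok,
        tie, and the three fold changes of interest (treatment effect in
        controls, knockout effect under vehicle, knockout effect under
        treatment), computed on the profiles (identical on raw counts —
        per-row scaling cancels).
        """
        check_is_fitted(self, "templates_")
        P = self._profiles(X)
        s = self.settings_
        n = P.shape[0]

        # vectorized correlation of every row against every template
        Pc = P - P.mean(axis=1, keepdims=True)
        Pn = np.linalg.norm(Pc, axis=1)
        R = np.zeros((n, len(self.templates_)))
        for j, tpl in enumerate(self.templates_):
            t = np.asarray(tpl.values)
            tc = t - t.mean()
            tn = np.linalg.norm(tc)
            with np.errstate(invalid="ignore", divide="ignore"):
                R[:, j] = (Pc @ tc) / (Pn * tn)
        R = np.clip(R, -1.0, 1.0)
        R2 = R * R
        with np.errstate(divide="ignore"):
            tstat = np.abs(R) * np.sqrt(_DF / np.maximum(1.0 - R2, 0.0))
        Pval = np.where(R2 >= 1.0, _P_FLOOR, np.maximum(2.0 * stats.t.sf(tstat, _DF), _P_FLOOR))

        rows = []
        for i in range(n):
            prof = P[i]
            flat = Pn[i] == 0  # zero-variance profile: no defined correlation
            max_pair_diff = float(prof.max() - prof.min())
            all_agree = max_pair_diff <= s.nochange_threshold + _EPS

            category = "unclassified"
            best_name = ""
            best_r = best_r2 = best_p = float("nan")
            tie = False
            change_ok = nochange_ok = False

            if not flat:
                # candidates: positive correlation with the template's own direction
                cand = [j for j in range(len(self.templates_)) if R[i, j] > 0]
                if cand:
                    best_r2_val = max(R2[i, j] for j in cand)
                    top = [j for j in cand if best_r2_val - R2[i, j] <= _TIE_TOL]
                    families = {self.templates_[j].category.split("-")[0] for j in top}
                    tie = len(families) > 1
                    j = top[0]
                    tpl = self.templates_[j]
                    best_name = tpl.category
                    best_r, best_r2, best_p = float(R[i, j]), float(R2[i, j]), float(Pval[i, j])
                    unchanged = [k for k in range(N_GROUPS) if k not in tpl.changed]
                    base = prof[unchanged].mean()
                    deviations = (prof[list(tpl.changed)] - base) * tpl.direction
                    change_ok = bool((deviations >= s.change_threshold - _EPS).all())
                    nochange_ok = bool(
                        prof[unchanged].max() - prof[unchanged].min() <= s.nochange_threshold + _EPS
                    )
                    if (not tie) and best_p < s.alpha and change_ok and nochange_ok:
                        category = tpl.category
            if category == "unclassified" and all_agree:
                category = "null"

            cv, cg, kv, kg = prof
            rows.append(
                {
                    "category": category,
                    "template": best_name,
                    "r": best_r,
                    "r2": best_r2,
                    "p": best_p,
                    "change_ok": change_ok,
                    "nochange_ok": nochange_ok,
                    "tie": tie,
                    "fold_glp2_ctrl": cg / cv if cv > 0 else np.nan,
                    "fold_ko_vehicle": kv / cv if cv > 0 else np.nan,
                    "fold_ko_glp2": kg / cg if cg > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def classify(profile, templates=None, settings: ClassifierSettings | None = None) -> dict:
    """Classify one normalized profile; returns the evidence row as a dict."""
    s = settings or ClassifierSettings()
    clf = TemplatePatternClassifier(
        baseline=s.baseline,
        change_threshold=s.change_threshold,
        nochange_threshold=s.nochange_threshold,
        floor=s.floor,
        alpha=s.alpha,
        normalize=False,
    ).fit()
    if templates is not None:
        clf.templates_ = list(templates)
    detail = clf.predict_detail(np.asarray(profile, dtype=float)[None, :])
    return detail.iloc[0].to_dict()


def classify_table(
    table: SpectralCountTable,
    settings: ClassifierSettings | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every protein of a count table.

    All-zero proteins are excluded (returned separately) rather than
    aborting the run.  The result frame has one row per classified protein,
    input order preserved.
    """
    s = settings or ClassifierSettings()
    counts = table.counts()
    zero = counts.max(axis=1) == 0
    excluded = table.protein_ids[zero].tolist()
    kept = table.data[~zero].reset_index(drop=True)

    clf = TemplatePatternClassifier(
        baseline=s.baseline,
        change_threshold=s.change_threshold,
        nochange_threshold=s.nochange_threshold,
        floor=s.floor,
        alpha=s.alpha,
    ).fit()
    detail = clf.predict_detail(counts[~zero])
    profiles = ProfileNormalizer(s.floor).fit(counts[~zero]).transform(counts[~zero])
    out = pd.concat(
        [
            kept[["protein_id", "gene_symbol"]],
            pd.DataFrame(profiles, columns=[f"norm_{g}" for g in GROUP_ORDER]),
            detail,
        ],
        axis=1,
    )
    return out, excluded


def fold_change(values, numerator_group: str, denominator_group: str) -> float:
    """Plain ratio between two groups of a four-value vector.

    ``values`` may be raw counts or a normalized profile — the per-protein
    scaling cancels.  A zero denominator yields ``nan`` (flagged, not an
    abort).
    """
    v = np.asarray(values, dtype=float)
    i = GROUP_ORDER.index(numerator_group)
    j = GROUP_ORDER.index(denominator_group)
    if v[j] == 0:
        return float("nan")
    return float(v[i] / v[j])
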