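"""Supporting quantification conventions for the 2x2 factorial design.

* two-way fixed-effects ANOVA (genotype x treatment) with Sidak-adjusted
  cell-wise post-hoc comparisons,
* 2^-ddCT relative quantification for qPCR (classic efficiency-2 form, no
  efficiency correction),
* densitometry normalization to the vehicle-treated control group via a
  paired internal loading control.

Unbalanced designs use type-II sums of squares: the 2x2 design implies no
ordering of factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .tables import CtTable, MeasurementTable

#: the four cell-wise comparisons of interest in the 2x2 design
POSTHOC_PAIRS = (
    (("ctrl", "vehicle"), ("ctrl", "glp2")),
    (("ko", "vehicle"), ("ko", "glp2")),
    (("ctrl", "vehicle"), ("ko", "vehicle")),
    (("ctrl", "glp2"), ("ko", "glp2")),
)


@dataclass
class AnovaResult:
    """Type-II two-way ANOVA table plus Sidak post-hoc comparisons.

    ``table`` rows: genotype, treatment, interaction, residual with columns
    sum_sq, df, F, p.  ``posthoc`` has one row per cell-wise comparison with
    the raw and Sidak-adjusted p (family size m = comparisons performed).
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame

    @property
    def p_genotype(self) -> float:
        return float(self.table.loc["genotype", "p"])

    @property
    def p_treatment(self) -> float:
        return float(self.table.loc["treatment", "p"])

    @property
    def p_interaction(self) -> float:
        return float(self.table.loc["interaction", "p"])


def two_way_anova(measurements: MeasurementTable) -> AnovaResult:
    """Fixed-effects 2x2 ANOVA of value ~ genotype * treatment.

    Requires both factors at both levels with >= 2 observations per cell
    and non-degenerate residual variance.  On balanced data the type-II
    decomposition equals the textbook closed-form sums of squares.
    """
    df = measurements.data
    cells = df.groupby(["genotype", "treatment"], observed=True).size()
    if len(cells) < 4:
        raise ValueError("every genotype x treatment cell must be populated")
    if (cells < 2).any():
        raise ValueError("need >= 2 observations per cell")

    model = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
    if model.ssr <= 1e-12 * max(model.centered_tss, 1.0):
        raise ValueError("degenerate data: zero residual variance")
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(genotype)": "genotype",
            "C(treatment)": "treatment",
            "C(genotype):C(treatment)": "interaction",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )[["sum_sq", "df", "F", "p"]]

    mse = aov.loc["residual", "sum_sq"] / aov.loc["residual", "df"]
    df_resid = aov.loc["residual", "df"]
    means = df.groupby(["genotype", "treatment"], observed=True)["value"].agg(["mean", "size"])
    rows = []
    m = len(POSTHOC_PAIRS)
    for a, b in POSTHOC_PAIRS:
        ma, na = means.loc[a, "mean"], means.loc[a, "size"]
        mb, nb = means.loc[b, "mean"], means.loc[b, "size"]
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        t = (mb - ma) / se
        p = 2.0 * stats.t.sf(abs(t), df_resid)
        rows.append(
            {
                "group_a": "_".join(a),
                "group_b": "_".join(b),
                "diff": mb - ma,
                "t": t,
                "p": p,
                "p_sidak": sidak_adjust(p, m),
                "m": m,
            }
        )
    return AnovaResult(table=aov, posthoc=pd.DataFrame(rows))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment 1 - (1 - p)^m, capped at 1."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(min(1.0 - (1.0 - p) ** m, 1.0))


def ddct_fold(ct: CtTable, control_group: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2^-ddCT relative quantification against ``control_group``.

    dCT = CT_target - CT_reference per sample; ddCT = dCT - mean dCT of the
    control group; fold = 2^-ddCT.  Returns (per-sample frame, per-group
    mean-fold frame).  The control group's mean ddCT is 0 by construction,
    so its geometric-mean fold is 1.
    """
    df = ct.data.copy()
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} absent from CT table")
    if df["ct_reference"].isna().any():
        bad = df.loc[df["ct_reference"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing reference CT for samples: {bad}")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    control_mean_dct = df.loc[df["group"] == control_group, "dct"].mean()
    df["ddct"] = df["dct"] - control_mean_dct
    df["fold"] = 2.0 ** (-df["ddct"])
    groups = (
        df.groupby("group", observed=True)["fold"]
        .agg(mean_fold="mean", n="size")
        .reset_index()
    )
    return df, groups


def normalize_to_vehicle_control(
    values,
    internal_control_values,
    group_labels,
    control_label: str = "ctrl_vehicle",
) -> np.ndarray:
    """Densitometry convention: ratio to paired loading control, then to the
    vehicle-treated control group's mean ratio (whose mean becomes 1)."""
    v = np.asarray(values, dtype=float)
    ic = np.asarray(internal_control_values, dtype=float)
    labels = np.asarray(group_labels)
    if v.shape != ic.shape or v.shape != labels.shape:
        raise ValueError("values, internal controls and labels must align")
    if (ic <= 0).any():
        raise ValueError("internal-control values must be strictly positive")
    control = labels == control_label
    if not control.any():
        raise ValueError(f"no samples labeled {control_label!r}")
    ratios = v / ic
    return ratios / ratios[control].mean()
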