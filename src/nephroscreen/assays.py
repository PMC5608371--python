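"""Small-assay statistics: relative qPCR, creatinine normalization,
group tests and the tissue-expression median comparison.

Relative qPCR quantification uses the comparative-Ct convention:
fold = 2^(-ddCt) with dCt = target Ct - reference-gene Ct and ddCt the
difference to the referent group's mean dCt, so the referent group has
geometric-mean fold 1 by construction.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


def relative_expression(
    records: pd.DataFrame, referent_group: str
) -> pd.Series:
    """Per-sample 2^(-ddCt) fold values relative to a referent group.

    ``records`` needs columns ``sample_id``, ``group``, ``target_ct``
    and ``reference_ct`` (cycles, in (0, 45)); samples with a missing
    reference Ct are dropped with a warning.
    """
    rec = records.copy()
    missing = rec["reference_ct"].isna() | rec["target_ct"].isna()
    if missing.any():
        logger.warning("dropping %d samples with missing Ct values", int(missing.sum()))
        rec = rec[~missing]
    for col in ("target_ct", "reference_ct"):
        bad = (rec[col] <= 0) | (rec[col] >= 45)
        if bad.any():
            raise ValueError(f"{col} outside the valid cycle range (0, 45)")
    if not (rec["group"] == referent_group).any():
        raise ValueError(f"referent group {referent_group!r} absent from records")

    d_ct = rec["target_ct"] - rec["reference_ct"]
    ref_mean = d_ct[rec["group"] == referent_group].mean()
    dd_ct = d_ct - ref_mean
    fold = np.exp2(-dd_ct)
    fold.index = rec["sample_id"]
    return fold.rename("relative_expression")


def normalize_to_creatinine(
    analyte_ng_ml: float | np.ndarray, creatinine_mg_ml: float | np.ndarray
) -> float | np.ndarray:
    """Urinary analyte concentration per mg creatinine (ng/mg)."""
    creatinine = np.asarray(creatinine_mg_ml, dtype=float)
    if (creatinine <= 0).any():
        raise ValueError("creatinine must be positive")
    out = np.asarray(analyte_ng_ml, dtype=float) / creatinine
    return float(out) if out.ndim == 0 else out


def _degenerate(groups: list[np.ndarray]) -> float | None:
    """p-value for the zero-variance corner cases, None otherwise."""
    if all(np.var(g) == 0.0 for g in groups):
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            return 1.0
        logger.warning("zero variance with unequal means; reporting p=0")
        return 0.0
    return None


def group_compare(
    values: Sequence[float],
    design: pd.DataFrame,
    scheme: str = "auto",
) -> pd.DataFrame:
    """Two-group t-test, one-way ANOVA, or 2x2 two-way ANOVA.

    ``design`` has one row per value; a single ``group`` column selects
    a t-test (2 groups) or one-way ANOVA (>2 groups), while ``strain``
    and ``treatment`` columns select a two-way ANOVA with main effects
    and interaction.  ``scheme`` may force ``ttest``, ``anova1`` or
    ``anova2``.  Returns a table of (effect, p) rows.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != len(design):
        raise ValueError("values and design must have equal length")

    if scheme == "auto":
        if {"strain", "treatment"} <= set(design.columns):
            scheme = "anova2"
        else:
            scheme = "ttest" if design["group"].nunique() == 2 else "anova1"

    if scheme in ("ttest", "anova1"):
        labels = design["group"].to_numpy()
        groups = [y[labels == g] for g in pd.unique(labels)]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError("need >= 2 groups with >= 2 values each")
        p_degen = _degenerate(groups)
        if p_degen is not None:
            return pd.DataFrame({"effect": [scheme], "p": [p_degen]})
        if scheme == "ttest":
            if len(groups) != 2:
                raise ValueError("t-test requires exactly 2 groups")
            p = float(stats.ttest_ind(groups[0], groups[1]).pvalue)
        else:
            p = float(stats.f_oneway(*groups).pvalue)
        return pd.DataFrame({"effect": [scheme], "p": [p]})

    if scheme == "anova2":
        frame = design.copy()
        frame["y"] = y
        cells = [g.to_numpy() for _, g in frame.groupby(["strain", "treatment"])["y"]]
        if any(len(c) < 2 for c in cells):
            raise ValueError("each strain x treatment cell needs >= 2 values")
        p_degen = _degenerate(cells)
        if p_degen is not None:
            return pd.DataFrame(
                {"effect": ["strain", "treatment", "strain:treatment"], "p": [p_degen] * 3}
            )
        model = smf.ols("y ~ C(strain) * C(treatment)", data=frame).fit()
        table = sm.stats.anova_lm(model, typ=2)
        return pd.DataFrame(
            {
                "effect": ["strain", "treatment", "strain:treatment"],
                "p": [
                    float(table.loc["C(strain)", "PR(>F)"]),
                    float(table.loc["C(treatment)", "PR(>F)"]),
                    float(table.loc["C(strain):C(treatment)", "PR(>F)"]),
                ],
            }
        )

    raise ValueError(f"unknown scheme {scheme!r}")


def tissue_median_compare(
    table: pd.DataFrame,
    focal: str,
    others: Sequence[str],
    gene: str | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of a focal tissue against each other tissue.

    ``table`` needs columns ``tissue``, ``gene`` and ``fpkm`` (replicate
    values).  Each (focal vs. other) pair gets a two-sided exact (or, for
    tied/large samples, normal-approximation) Mann-Whitney U p-value;
    Bonferroni adjustment multiplies by the number of tests performed in
    this call (reported in column ``m``), capped at 1.  All-tied inputs
    give p = 1.
    """
    sub = table if gene is None else table[table["gene"] == gene]

    def vals(tissue: str) -> np.ndarray:
        v = sub.loc[sub["tissue"] == tissue, "fpkm"].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 2 replicate values")
        if (v < 0).any():
            raise ValueError("FPKM values must be >= 0")
        return v

    focal_vals = vals(focal)
    rows = []
    m = len(others)
    for other in others:
        other_vals = vals(other)
        pooled = np.concatenate([focal_vals, other_vals])
        if np.all(pooled == pooled[0]):
            p_raw = 1.0
        else:
            method = "exact" if len(pooled) <= 20 else "asymptotic"
            p_raw = float(
                stats.mannwhitneyu(
                    focal_vals, other_vals, alternative="two-sided", method=method
                ).pvalue
            )
        rows.append(
            {
                "focal": focal,
                "other": other,
                "p_raw": p_raw,
                "m": m,
                "p_bonferroni": min(1.0, p_raw * m),
            }
        )
    return pd.DataFrame(rows)
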