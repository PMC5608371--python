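"""Intensity normalization and differential-expression screening.

The screen implemented here is the classic microarray recipe for small
factorial designs: quantile-normalize the per-sample intensity
distributions, collapse probes to unique gene symbols, then flag genes
whose linear fold change between a test and a referent group is at least
2 (or at most 0.5) with a Benjamini-Hochberg adjusted p-value below
``alpha``.  P-values come from a Welch (unequal-variance) two-sample
t-test on log2 intensities, the standard choice for 4-vs-4 group sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STRAINS = ("susceptible", "resistant")
TREATMENTS = ("control", "diabetic")

#: the four screens: name -> (test (strain, treatment), referent (strain, treatment))
COMPARISONS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "susceptible_dm": (("susceptible", "diabetic"), ("susceptible", "control")),
    "resistant_dm": (("resistant", "diabetic"), ("resistant", "control")),
    "strain_ctrl": (("susceptible", "control"), ("resistant", "control")),
    "strain_dm": (("susceptible", "diabetic"), ("resistant", "diabetic")),
}


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with its 2x2 factorial design.

    Parameters
    ----------
    values
        Nonnegative intensities, rows indexed by probe id, columns by
        sample id (arbitrary fluorescence units).
    gene_symbols
        Gene symbol per probe, aligned with ``values.index``.
    design
        One row per sample (index = sample id) with columns ``strain``
        (``susceptible`` / ``resistant``) and ``treatment`` (``control``
        / ``diabetic``).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        if self.values.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        missing = self.values.columns.difference(self.design.index)
        if len(missing):
            raise ValueError(f"samples missing from design: {list(missing)}")
        bad_strain = set(self.design["strain"]) - set(STRAINS)
        bad_treat = set(self.design["treatment"]) - set(TREATMENTS)
        if bad_strain or bad_treat:
            raise ValueError(
                f"unknown design labels: strains={bad_strain or '{}'} "
                f"treatments={bad_treat or '{}'}"
            )
        self.design = self.design.loc[self.values.columns]

    # -- convenience ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, strain: str, treatment: str) -> list[str]:
        """Sample ids belonging to one (strain, treatment) group."""
        mask = (self.design["strain"] == strain) & (self.design["treatment"] == treatment)
        return list(self.design.index[mask])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.gene_symbols.copy(), self.design.copy())


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common distribution of rank means.

    After the call each column's sorted values equal the cross-sample
    mean of order statistics.  Ties within a column receive the mean of
    the reference values at their tied ranks (the ``ties=TRUE``
    convention of limma's ``normalizeBetweenArrays``).  Row and column
    labels are preserved.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(X).all():
        bad = matrix.values.index[~np.isfinite(X).all(axis=1)]
        raise ValueError(f"non-finite intensities at probes: {list(bad[:5])}")

    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)

    out = np.empty_like(X)
    n = X.shape[0]
    ranks_template = np.empty(n)
    for j in range(X.shape[1]):
        col = X[:, j]
        # mean reference value over tied ranks, assigned back per probe
        sorted_col = col[order[:, j]]
        ranks = ranks_template.copy()
        ranks[order[:, j]] = np.arange(n)
        # average the reference over runs of equal intensity
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        ref_tied = np.empty(n)
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        for s, e in zip(starts, ends):
            ref_tied[s:e] = (csum[e] - csum[s]) / (e - s)
        out[:, j] = ref_tied[ranks.astype(int)]

    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def collapse_to_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep one probe per gene symbol: the one with the highest mean intensity.

    Ties are broken by lexicographically smaller probe id; probes with an
    empty or missing symbol are dropped with a warning.
    """
    symbols = matrix.gene_symbols.fillna("").astype(str)
    empty = symbols.str.strip() == ""
    if empty.any():
        logger.warning("dropping %d probes without a gene symbol", int(empty.sum()))
    keep = matrix.values.index[~empty]

    means = matrix.values.loc[keep].mean(axis=1)
    chooser = pd.DataFrame(
        {"gene": symbols.loc[keep], "mean": means, "probe": keep.astype(str)}
    )
    # highest mean wins; ties -> lexicographically smaller probe id
    chooser = chooser.sort_values(
        ["gene", "mean", "probe"], ascending=[True, False, True], kind="stable"
    )
    winners = chooser.drop_duplicates("gene", keep="first").set_index("probe")

    values = matrix.values.loc[winners.index]
    values.index = pd.Index(winners["gene"], name="gene")
    gene_symbols = pd.Series(winners["gene"].to_numpy(), index=values.index)
    return ExpressionMatrix(values, gene_symbols, matrix.design.copy())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``adj(i) = min_{j: rank(j) >= rank(i)} p(j) * m / rank(j)``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_log2_pvalue(test: np.ndarray, referent: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on log2 intensities.

    Degenerate variance is resolved deterministically: equal means give
    p = 1, unequal means with zero pooled variance give p = 0 (flagged).
    """
    a = np.log2(test)
    b = np.log2(referent)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        logger.warning("zero variance with unequal means; reporting p=0")
        return 0.0
    with warnings.catch_warnings():
        # near-tied values after quantile normalization trip scipy's
        # catastrophic-cancellation warning; the degenerate cases are
        # already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return 1.0 if np.isnan(p) else p


def differential_expression(
    matrix: ExpressionMatrix,
    test_group: tuple[str, str],
    referent_group: tuple[str, str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen every gene for differential expression between two groups.

    Fold change is the ratio of linear-scale group means
    (test / referent); significance requires fold change >= fc_threshold
    or <= 1/fc_threshold together with a BH-adjusted Welch-t p-value
    below ``alpha``.

    The analysis is restricted to the fold-change-passing genes before
    multiple-testing adjustment: BH runs over that family only, which is
    the screen's testing population.  Genes outside the restriction
    report ``p_adj`` = 1 and are never significant.

    Returns a DataFrame indexed by gene with columns ``mean_referent``,
    ``mean_test``, ``fold_change``, ``log2_fc``, ``p_raw``, ``p_adj``,
    ``direction`` (up/down/none) and ``significant``.
    """
    if fc_threshold <= 0 or not (0 < alpha < 1):
        raise ValueError("fc_threshold must be positive and alpha in (0,1)")
    test_ids = matrix.group_samples(*test_group)
    ref_ids = matrix.group_samples(*referent_group)
    if not test_ids or not ref_ids:
        missing = test_group if not test_ids else referent_group
        raise ValueError(f"empty group {missing!r}")

    T = matrix.values[test_ids].to_numpy(dtype=float)
    R = matrix.values[ref_ids].to_numpy(dtype=float)
    mean_test = T.mean(axis=1)
    mean_ref = R.mean(axis=1)
    if (mean_ref == 0).any():
        raise ValueError("zero referent mean intensity; fold change undefined")

    fold = mean_test / mean_ref
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(fold)

    p_raw = np.array(
        [welch_log2_pvalue(T[i], R[i]) for i in range(T.shape[0])]
    )

    passes_fc = (fold >= fc_threshold) | (fold <= 1.0 / fc_threshold)
    p_adj = np.ones_like(p_raw)
    if passes_fc.any():
        p_adj[passes_fc] = bh_adjust(p_raw[passes_fc])
    significant = passes_fc & (p_adj < alpha)
    direction = np.where(
        significant & (fold >= fc_threshold),
        "up",
        np.where(significant, "down", "none"),
    )

    return pd.DataFrame(
        {
            "mean_referent": mean_ref,
            "mean_test": mean_test,
            "fold_change": fold,
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
            "significant": significant,
        },
        index=matrix.values.index.rename("gene"),
    )
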