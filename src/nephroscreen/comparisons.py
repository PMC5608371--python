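"""Four-way comparison logic over a 2-strain x 2-treatment design.

The design crosses a nephropathy-susceptible and a nephropathy-resistant
mouse strain with control vs. diabetic treatment.  Four screens are run
against fixed referent conventions:

* ``susceptible_dm`` - diabetic vs. control (referent), susceptible strain
* ``resistant_dm``   - diabetic vs. control (referent), resistant strain
* ``strain_ctrl``    - control susceptible vs. resistant (referent)
* ``strain_dm``      - diabetic susceptible vs. resistant (referent)

The exclusive sets are the genes significantly different between the
diabetic strains but not between the control strains: the candidate
susceptibility genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import COMPARISONS, ExpressionMatrix, differential_expression

logger = logging.getLogger(__name__)


@dataclass
class ComparisonQuad:
    """The four differential-expression screens, one DataFrame each."""

    susceptible_dm: pd.DataFrame
    resistant_dm: pd.DataFrame
    strain_ctrl: pd.DataFrame
    strain_dm: pd.DataFrame

    def __getitem__(self, name: str) -> pd.DataFrame:
        if name not in COMPARISONS:
            raise KeyError(name)
        return getattr(self, name)

    def counts(self) -> pd.DataFrame:
        """Up/down significant-gene counts per screen (the Venn numbers)."""
        rows = {}
        for name in COMPARISONS:
            de = self[name]
            rows[name] = {
                "up": int((de["direction"] == "up").sum()),
                "down": int((de["direction"] == "down").sum()),
            }
        return pd.DataFrame(rows).T


@dataclass
class ExclusiveSets:
    """Strain-difference genes present only under diabetes.

    ``up_exclusive`` / ``down_exclusive`` are genes up- or down-regulated
    in the diabetic strain comparison that are not significant (either
    direction) in the control strain comparison.
    """

    up_exclusive: list[str]
    down_exclusive: list[str]

    @property
    def all_genes(self) -> list[str]:
        return self.up_exclusive + self.down_exclusive


def run_four_comparisons(
    matrix: ExpressionMatrix, fc_threshold: float = 2.0, alpha: float = 0.05
) -> ComparisonQuad:
    """Run the four screens with their fixed referent conventions.

    ``matrix`` should already be quantile-normalized and collapsed to
    unique genes; BH adjustment is applied within each screen separately.
    """
    for strain in ("susceptible", "resistant"):
        for treatment in ("control", "diabetic"):
            if not matrix.group_samples(strain, treatment):
                raise ValueError(f"missing design group: ({strain}, {treatment})")
    results = {
        name: differential_expression(matrix, test, referent, fc_threshold, alpha)
        for name, (test, referent) in COMPARISONS.items()
    }
    return ComparisonQuad(**results)


def exclusive_sets(quad: ComparisonQuad) -> ExclusiveSets:
    """Diabetic strain-difference genes not different between control strains."""
    strain_dm = quad.strain_dm
    ctrl_sig = set(quad.strain_ctrl.index[quad.strain_ctrl["significant"]])

    up = [g for g in strain_dm.index[strain_dm["direction"] == "up"] if g not in ctrl_sig]
    down = [g for g in strain_dm.index[strain_dm["direction"] == "down"] if g not in ctrl_sig]

    result = ExclusiveSets(up_exclusive=up, down_exclusive=down)
    # invariant asserted on every run: exclusivity w.r.t. the control screen
    overlap = set(result.all_genes) & ctrl_sig
    assert not overlap, f"exclusive sets intersect control-strain hits: {overlap}"
    return result


def exclusive_table(quad: ComparisonQuad, sets: ExclusiveSets) -> pd.DataFrame:
    """Two-column (gene, fold_change) table of the exclusive genes.

    Fold changes come from the diabetic strain comparison; up-regulated
    genes first in descending order, then down-regulated ascending.
    """
    fc = quad.strain_dm["fold_change"]
    up = fc.loc[sets.up_exclusive].sort_values(ascending=False)
    down = fc.loc[sets.down_exclusive].sort_values(ascending=False)
    table = pd.concat([up, down]).rename("fold_change").to_frame()
    table.insert(0, "regulation", ["up"] * len(up) + ["down"] * len(down))
    return table


def heatmap_matrix(
    matrix: ExpressionMatrix,
    genes: list[str],
    referent_group: tuple[str, str] = ("resistant", "diabetic"),
    order_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample log2 ratios to the referent group's mean intensity.

    Entries are ``log2(intensity / mean referent intensity)`` for the
    supplied genes so the referent group's row means are 0 in log2 space.
    Rows are ordered by ``order_by`` (descending; typically the diabetic
    strain-comparison fold change), or left in the given order.
    """
    ref_ids = matrix.group_samples(*referent_group)
    if not ref_ids:
        raise ValueError(f"empty referent group {referent_group!r}")
    genes = [g for g in genes if g in matrix.values.index]
    sub = matrix.values.loc[genes]
    ref_mean = sub[ref_ids].mean(axis=1)
    usable = ref_mean > 0
    if (~usable).any():
        logger.warning(
            "dropping %d genes with zero referent mean", int((~usable).sum())
        )
    sub = sub.loc[usable]
    heat = np.log2(sub.div(ref_mean.loc[usable], axis=0))
    if order_by is not None:
        ordering = order_by.reindex(heat.index).sort_values(ascending=False).index
        heat = heat.loc[ordering]
    return heat
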