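"""Hypergeometric gene-set over-representation analysis.

For a hit list of n genes mappable to a universe of N objects, a set of
R members that intersects the hits in r genes is scored by the
upper-tail probability P(X >= r) with X ~ Hypergeometric(N, R, n):
the chance of at least as large an overlap when n objects are drawn
without replacement.  The per-set p-values receive a Benjamini-Hochberg
"minimum FDR" column over all sets tested in the run.  Only
over-representation is scored; depletion is not reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetDatabase:
    """Named gene sets over a fixed universe of N objects."""

    universe: set[str]
    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def n_objects(self) -> int:
        return len(self.universe)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetDatabase:
    """Read a GMT file (set name, description, tab-separated members).

    If ``universe`` is omitted it defaults to the union of all members.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 fields): {line[:60]!r}")
        name, desc, *members = parts
        sets[name] = {m for m in members if m}
        descriptions[name] = desc
    uni = set(universe) if universe is not None else set().union(*sets.values(), set())
    return GeneSetDatabase(universe=uni, sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDatabase, path: str | Path) -> None:
    lines = []
    for name in sorted(db.sets):
        desc = db.descriptions.get(name, "")
        members = "\t".join(sorted(db.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(r: int, n: int, R: int, N: int) -> float:
    """Upper-tail P(X >= r) for X ~ Hypergeometric(N, R, n), in log space.

    ``r`` intersecting objects, ``n`` drawn objects, ``R`` marked set
    size, ``N`` universe size.  P(X >= 0) is exactly 1.
    """
    if not (0 <= r <= min(n, R) and 0 <= n <= N and 0 <= R <= N):
        raise ValueError(
            f"inconsistent counts: r={r}, n={n}, R={R}, N={N} "
            "(need 0 <= r <= min(n, R), n <= N, R <= N)"
        )
    if r == 0:
        return 1.0
    k = np.arange(r, min(n, R) + 1)
    log_terms = _log_binom(R, k) + _log_binom(N - R, n - k) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_genelist(
    hits: Iterable[str],
    db: GeneSetDatabase,
) -> pd.DataFrame:
    """Score every set in the database against a hit list.

    Hits outside the universe are dropped (with a logged count); ``n``
    is the number of mappable hits.  Returns one row per set with
    columns ``r``, ``n``, ``R``, ``N``, ``p`` and ``min_fdr`` (BH over
    all sets tested), sorted by ascending p then set name.
    """
    hits = set(hits)
    mapped = hits & db.universe
    dropped = len(hits) - len(mapped)
    if dropped:
        logger.info("dropped %d hit genes not mappable to the universe", dropped)
    if not mapped:
        raise ValueError(
            "no hit genes map to the database universe; "
            "check gene identifier conventions"
        )
    n = len(mapped)
    N = db.n_objects
    rows = []
    for name, members in db.sets.items():
        r = len(mapped & members)
        R = len(members)
        rows.append(
            {
                "set_name": name,
                "r": r,
                "n": n,
                "R": R,
                "N": N,
                "p": hypergeometric_tail(r, n, R, N),
            }
        )
    table = pd.DataFrame(rows)
    table["min_fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "set_name"], kind="stable").set_index("set_name")
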