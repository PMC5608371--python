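"""Leukocyte rolling / adhesion / transmigration classification under shear.

Tracked cells from a microfluidic vascular network are labelled by the
recruitment-cascade stage they exhibit:

* transmigrated - the cell crossed into the tissue compartment;
* adherent      - the cell stayed within a displacement tolerance for at
  least 30 seconds;
* rolling       - the cell kept moving but below the critical velocity
  of its vessel segment;
* free          - everything else (freely flowing).

The critical velocity follows the hemodynamic convention
``v_crit = v_cc * eps * (2 - eps)`` where ``v_cc`` is the centerline
velocity of the segment and ``eps`` the cell-to-vessel diameter ratio:
a cell rolling on the wall would, if freely carried by a parabolic
(Poiseuille) profile at one cell radius from the wall, travel exactly at
``v_crit``; slower cells are interacting with the endothelium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CELL_DIAMETER_UM = 7.5  # human neutrophil

CLASSES = ("free", "rolling", "adherent", "transmigrated")


@dataclass
class VesselSegment:
    """One channel of the vascular network.

    ``v_cc`` is the centerline velocity in um/s (supplied by flow
    modelling or estimated from observed cell speeds); ``shear_rate`` in
    1/s may be supplied or derived from geometry.
    """

    segment_id: str
    diameter: float  # um
    v_cc: float | None = None  # um/s
    shear_rate: float | None = None  # 1/s

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"segment {self.segment_id}: diameter must be positive")
        if self.v_cc is not None and self.v_cc < 0:
            raise ValueError(f"segment {self.segment_id}: v_cc must be >= 0")


def critical_velocity(v_cc: float, cell_diameter: float, vessel_diameter: float) -> float:
    """``v_cc * eps * (2 - eps)`` with ``eps = cell_diameter / vessel_diameter``."""
    if cell_diameter <= 0 or vessel_diameter <= 0:
        raise ValueError("diameters must be positive")
    eps = cell_diameter / vessel_diameter
    if eps > 1:
        raise ValueError("cell larger than vessel (eps > 1)")
    if v_cc < 0:
        raise ValueError("v_cc must be >= 0")
    return v_cc * eps * (2.0 - eps)


def _per_cell_speeds(traj: pd.DataFrame) -> pd.DataFrame:
    """Mean frame-to-frame speed (um/s) and majority segment per cell."""
    rows = []
    for cell_id, g in traj.groupby("cell_id", sort=False):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(dtype=float)
        if (np.diff(t) <= 0).any():
            raise ValueError(f"cell {cell_id}: times must be strictly increasing")
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError(f"cell {cell_id}: non-finite positions")
        if len(t) < 2:
            speed = 0.0
        else:
            step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            speed = float(step.sum() / (t[-1] - t[0]))
        seg_counts = g["segment_id"].value_counts()
        if len(seg_counts) > 1:
            logger.warning(
                "cell %s spans %d segments; using longest residence",
                cell_id,
                len(seg_counts),
            )
        rows.append(
            {
                "cell_id": cell_id,
                "mean_velocity": speed,
                "segment_id": seg_counts.idxmax(),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def estimate_centerline_velocity(
    traj: pd.DataFrame, segment_id: str, q: float = 100.0
) -> float:
    """Centerline velocity estimate for one segment, in um/s.

    The q-th percentile (default the maximum) of per-cell mean
    frame-to-frame speeds within the segment; the fastest tracked cell
    approximates the centerline flow.  Lower ``q`` trades bias for
    robustness to tracking outliers.
    """
    sub = traj[traj["segment_id"] == segment_id]
    if sub.empty:
        raise ValueError(f"no cells observed in segment {segment_id!r}")
    speeds = _per_cell_speeds(sub)["mean_velocity"]
    return float(np.percentile(speeds.to_numpy(), q))


def _has_immobile_window(
    t: np.ndarray, xy: np.ndarray, window_s: float, delta_um: float
) -> bool:
    """True if some ``window_s``-long stretch has net displacement < delta."""
    j = np.searchsorted(t, t + window_s, side="left")
    valid = j < len(t)
    if not valid.any():
        return False
    starts = np.flatnonzero(valid)
    disp = np.linalg.norm(xy[j[starts]] - xy[starts], axis=1)
    return bool((disp < delta_um).any())


def classify_cells(
    traj: pd.DataFrame,
    segments: Sequence[VesselSegment],
    cell_diameter: float = DEFAULT_CELL_DIAMETER_UM,
    delta_um: float | None = None,
    adhesion_window_s: float = 30.0,
    v_cc_percentile: float = 100.0,
    global_v_cc: float | None = None,
) -> pd.DataFrame:
    """Assign each tracked cell a single recruitment-cascade label.

    Precedence: transmigrated > adherent > rolling > free.  A cell is
    transmigrated if any record carries region ``tissue``; adherent if
    some 30-s window has net displacement below ``delta_um`` (default
    one cell radius); rolling if its mean speed is below the critical
    velocity of its segment; free otherwise.  Segment centerline
    velocities are taken from the geometry when supplied, estimated from
    observed speeds otherwise, or overridden network-wide by
    ``global_v_cc``.

    Returns a DataFrame indexed by cell id with ``cls``,
    ``mean_velocity``, ``v_crit_used``, ``segment_id`` and ``t_cross``
    (time of first tissue record, NaN otherwise).
    """
    if delta_um is None:
        delta_um = cell_diameter / 2.0
    span = traj.groupby("cell_id")["t_s"].agg(lambda s: s.max() - s.min())
    if span.max() < adhesion_window_s:
        raise ValueError(
            f"observation window ({span.max():.1f} s) shorter than the "
            f"{adhesion_window_s:.0f}-s adhesion rule"
        )

    seg_map = {s.segment_id: s for s in segments}
    stats = _per_cell_speeds(traj)

    v_cc_by_segment: dict[str, float] = {}
    for seg_id in stats["segment_id"].unique():
        if global_v_cc is not None:
            v_cc_by_segment[seg_id] = global_v_cc
        elif seg_id in seg_map and seg_map[seg_id].v_cc is not None:
            v_cc_by_segment[seg_id] = float(seg_map[seg_id].v_cc)
        else:
            v_cc_by_segment[seg_id] = estimate_centerline_velocity(
                traj, seg_id, q=v_cc_percentile
            )

    records = []
    for cell_id, g in traj.groupby("cell_id", sort=False):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(dtype=float)
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        seg_id = stats.loc[cell_id, "segment_id"]
        if seg_id not in seg_map:
            raise KeyError(f"segment {seg_id!r} missing from geometry")
        seg = seg_map[seg_id]
        v_crit = critical_velocity(v_cc_by_segment[seg_id], cell_diameter, seg.diameter)

        tissue = g["region"].to_numpy() == "tissue"
        if tissue.any():
            cls = "transmigrated"
            t_cross = float(t[tissue.argmax()])
        else:
            t_cross = np.nan
            if _has_immobile_window(t, xy, adhesion_window_s, delta_um):
                cls = "adherent"
            elif stats.loc[cell_id, "mean_velocity"] < v_crit:
                cls = "rolling"
            else:
                cls = "free"
        records.append(
            {
                "cell_id": cell_id,
                "cls": cls,
                "mean_velocity": stats.loc[cell_id, "mean_velocity"],
                "v_crit_used": v_crit,
                "segment_id": seg_id,
                "t_cross": t_cross,
            }
        )
    return pd.DataFrame(records).set_index("cell_id")


def adhesion_by_shear(
    classifications: pd.DataFrame,
    segments: Sequence[VesselSegment],
    bins: Sequence[float],
) -> pd.Series:
    """Adherent-cell counts aggregated into wall-shear-rate bins (1/s).

    ``bins`` are edges as for ``numpy.histogram``; segments without a
    shear rate are excluded with a warning.
    """
    shear = {s.segment_id: s.shear_rate for s in segments}
    adherent = classifications[classifications["cls"] == "adherent"]
    rates = []
    for seg_id in adherent["segment_id"]:
        rate = shear.get(seg_id)
        if rate is None:
            logger.warning("segment %s has no shear rate; excluded", seg_id)
            continue
        rates.append(rate)
    counts, edges = np.histogram(rates, bins=np.asarray(bins, dtype=float))
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.Series(counts, index=labels, name="adherent_count")


def transmigration_summary(
    classifications_by_condition: Mapping[float, pd.DataFrame],
    timepoints_min: Sequence[float],
    untreated_dose: float = 0.0,
) -> pd.DataFrame:
    """Dose-response table of transmigration relative to untreated cells.

    For every dose and timepoint the number of cells that have crossed
    into tissue by that time is divided by the untreated (dose-0) count
    at the same timepoint; an undefined ratio (untreated count 0) is
    reported as NaN.  The rolling percentage per dose (rolling count /
    total cells) is included as the Fig-7B-style convention.

    Returns a DataFrame indexed by dose with one ``rel_transmigration_<t>min``
    column per timepoint plus ``pct_rolling``.
    """
    if untreated_dose not in classifications_by_condition:
        raise ValueError("an untreated (dose 0) condition is required")

    def crossed_by(cls: pd.DataFrame, t_min: float) -> int:
        mask = (cls["cls"] == "transmigrated") & (cls["t_cross"] <= t_min * 60.0)
        return int(mask.sum())

    baseline = {
        t: crossed_by(classifications_by_condition[untreated_dose], t)
        for t in timepoints_min
    }
    rows = {}
    for dose, cls in classifications_by_condition.items():
        row = {}
        for t in timepoints_min:
            if baseline[t] == 0:
                logger.warning("untreated transmigration count 0 at %g min", t)
                row[f"rel_transmigration_{t:g}min"] = np.nan
            else:
                row[f"rel_transmigration_{t:g}min"] = crossed_by(cls, t) / baseline[t]
        row["pct_rolling"] = 100.0 * (cls["cls"] == "rolling").mean()
        rows[dose] = row
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "dose_ng_ml"
    return out
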