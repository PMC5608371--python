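"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* ``generate_expression`` - a 2-strain x 2-treatment x n-replicate
  log2-normal intensity matrix with per-sample scale distortions (the
  artefact quantile normalization removes) and planted group-specific
  fold changes;
* ``generate_genesets`` - a GMT-writable gene-set database with exactly
  one set enriched for a planted hit list by construction;
* ``generate_trajectories`` - cell tracks through a network of
  parabolic-profile (Poiseuille) channels containing known free-flowing,
  rolling, adherent and transmigrating cells.

Ground truth is returned as a separate ``SimTruth`` sidecar, never
embedded in the data files themselves.  Every generator draws from one
explicit ``numpy.random.default_rng`` stream seeded from its config; no
global seed state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import COMPARISONS, STRAINS, TREATMENTS, ExpressionMatrix
from .enrichment import GeneSetDatabase
from .kinetics import DEFAULT_CELL_DIAMETER_UM, VesselSegment, critical_velocity

GROUPS = [(s, t) for s in STRAINS for t in TREATMENTS]

#: which (strain, treatment) group receives a planted effect for each screen
_EFFECT_TARGET: dict[str, tuple[str, str]] = {
    name: test for name, (test, _ref) in COMPARISONS.items()
}


@dataclass
class SimTruth:
    """Ground-truth sidecar for simulated data.

    Only the fields relevant to the generator that produced it are set.
    ``de_log2fc`` holds the true log2 group-mean difference per gene and
    screen; ``de_status`` its nonzero indicator.  ``enriched_sets`` names
    the sets enriched by construction.  ``cell_labels`` maps cell id to
    the intended recruitment-cascade class.
    """

    de_log2fc: pd.DataFrame | None = None
    de_status: pd.DataFrame | None = None
    enriched_sets: set[str] = field(default_factory=set)
    cell_labels: pd.Series | None = None


# ----------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------

@dataclass
class ExprSimConfig:
    """Configuration of the expression simulator.

    Intensities are ``2 ** (baseline + probe offset + planted effect *
    group indicator + sample scale offset + noise)``; all contributions
    are on the log2 scale.  ``planted_effects`` is a list of
    ``(gene_id, comparison_id, log2_effect)`` where the comparison id is
    one of the four screens; the effect is added to that screen's test
    group.
    """

    n_genes: int = 1000
    n_probes_per_gene: int = 1
    n_replicates: int = 4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.5
    sample_scale_log2_sd: float = 0.3
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_probes_per_gene < 1 or self.n_replicates <= 0:
            raise ValueError("counts must be positive (n_probes_per_gene >= 1)")
        for sd in (self.baseline_log2_sd, self.noise_log2_sd, self.sample_scale_log2_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for gene, comparison, effect in self.planted_effects:
            if comparison not in COMPARISONS:
                raise ValueError(
                    f"unknown comparison {comparison!r}; "
                    f"expected one of {sorted(COMPARISONS)}"
                )
            if not np.isfinite(effect):
                raise ValueError(f"non-finite effect for gene {gene!r}")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def planted_screen_config(
    n_genes: int = 1000,
    n_planted: int = 50,
    effect_log2: float = 2.5,
    comparison: str = "susceptible_dm",
    noise_log2_sd: float = 0.5,
    sample_scale_log2_sd: float = 0.3,
    seed: int = 7,
    **kwargs,
) -> ExprSimConfig:
    """Default benchmark config: 1,000 genes, 50 planted at |log2FC| = 2.5.

    Planted genes and effect signs are drawn from a dedicated stream so
    the choice is reproducible from the seed alone.
    """
    rng = np.random.default_rng(seed)
    cfg = ExprSimConfig(
        n_genes=n_genes,
        noise_log2_sd=noise_log2_sd,
        sample_scale_log2_sd=sample_scale_log2_sd,
        seed=seed,
        **kwargs,
    )
    genes = rng.choice(cfg.gene_ids(), size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    cfg.planted_effects = [
        (g, comparison, s * effect_log2) for g, s in zip(genes, signs)
    ]
    return cfg


def generate_expression(config: ExprSimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a probe x sample intensity matrix plus its truth sidecar."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}

    sample_ids, strains, treatments = [], [], []
    short = {"susceptible": "sus", "resistant": "res", "control": "ctrl", "diabetic": "dm"}
    for strain, treatment in GROUPS:
        for r in range(config.n_replicates):
            sample_ids.append(f"{short[strain]}_{short[treatment]}_{r + 1}")
            strains.append(strain)
            treatments.append(treatment)
    design = pd.DataFrame(
        {"strain": strains, "treatment": treatments}, index=pd.Index(sample_ids, name="sample_id")
    )

    # per-gene, per-group log2 offsets from the planted effects
    offsets = np.zeros((config.n_genes, len(GROUPS)))
    group_index = {g: j for j, g in enumerate(GROUPS)}
    for gene, comparison, effect in config.planted_effects:
        if gene not in gene_index:
            raise ValueError(f"planted gene {gene!r} not among generated genes")
        offsets[gene_index[gene], group_index[_EFFECT_TARGET[comparison]]] += effect

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    scale = rng.normal(0.0, config.sample_scale_log2_sd, len(sample_ids))

    group_of_sample = np.array([group_index[(s, t)] for s, t in zip(strains, treatments)])
    log2_signal = baseline[:, None] + offsets[:, group_of_sample] + scale[None, :]

    # expand genes to probes; later probes of a gene sit slightly lower so
    # the collapse rule (highest mean, lexicographic tie-break) is exercised
    probe_rows, probe_ids, probe_genes = [], [], []
    for g in genes:
        for k in range(config.n_probes_per_gene):
            probe_rows.append(gene_index[g])
            probe_ids.append(f"{g}_p{k + 1}")
            probe_genes.append(g)
    probe_shift = -0.05 * np.array(
        [k for _g in genes for k in range(config.n_probes_per_gene)]
    )
    log2_probe = log2_signal[probe_rows, :] + probe_shift[:, None]
    log2_probe = log2_probe + rng.normal(0.0, config.noise_log2_sd, log2_probe.shape)

    values = pd.DataFrame(
        np.exp2(log2_probe), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    matrix = ExpressionMatrix(
        values, pd.Series(probe_genes, index=values.index), design
    )

    # truth: true log2 difference per screen from the group offsets
    de_log2fc = pd.DataFrame(index=pd.Index(genes, name="gene"), dtype=float)
    for name, (test, referent) in COMPARISONS.items():
        de_log2fc[name] = offsets[:, group_index[test]] - offsets[:, group_index[referent]]
    truth = SimTruth(de_log2fc=de_log2fc, de_status=de_log2fc != 0.0)
    return matrix, truth


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def generate_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    planted_set: Sequence[str],
    seed: int = 0,
) -> tuple[GeneSetDatabase, SimTruth]:
    """Random gene sets plus one set equal to the planted hit list.

    The random sets are uniform draws from the universe, so only the
    planted set is enriched for the planted genes by construction.  An
    empty ``planted_set`` produces a database of random sets with no set
    flagged in the truth.
    """
    universe = list(dict.fromkeys(universe))
    planted = set(planted_set)
    if not planted <= set(universe):
        raise ValueError("planted_set must be a subset of the universe")
    lo, hi = set_size_range
    if not (0 < lo <= hi <= len(universe)):
        raise ValueError("set sizes must satisfy 0 < lo <= hi <= |universe|")

    rng = np.random.default_rng(seed)
    width = len(str(max(n_sets, 1)))
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"RANDOM_SET_{i + 1:0{width}d}"
        sets[name] = set(rng.choice(universe, size=size, replace=False))
        descriptions[name] = "random background set"
    enriched: set[str] = set()
    if planted:
        sets["PLANTED_SET"] = planted
        descriptions["PLANTED_SET"] = "set enriched by construction"
        enriched = {"PLANTED_SET"}

    db = GeneSetDatabase(universe=set(universe), sets=sets, descriptions=descriptions)
    return db, SimTruth(enriched_sets=enriched)


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

@dataclass
class TrajSimConfig:
    """Configuration of the cell-trajectory simulator.

    Channels carry a parabolic axial velocity profile
    ``v(r) = v_max * (1 - (r / Rv)^2)``; the wall shear rate recorded per
    segment follows the generator convention ``4 * v_max / diameter``.
    Free cells travel at radii where their advection speed clears the
    segment's critical velocity by a 20% margin, rolling cells move
    monotonically at (0.05, 0.8) x v_crit, adherent cells stay within
    ``adherent_jitter`` and transmigrating cells cross into the tissue
    compartment partway through the recording.
    """

    n_segments: int = 4
    segment_diameters: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0)  # um
    v_max_per_segment: tuple[float, ...] = (200.0, 300.0, 400.0, 500.0)  # um/s
    cell_diameter: float = DEFAULT_CELL_DIAMETER_UM
    frame_interval: float = 1.0 / 30.0  # s (30 fps video)
    duration: float = 60.0  # s
    n_cells_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"free": 10, "rolling": 10, "adherent": 10, "transmigrating": 10}
    )
    adherent_jitter: float = 0.5  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segment_diameters) != self.n_segments or len(
            self.v_max_per_segment
        ) != self.n_segments:
            raise ValueError("per-segment arrays must have n_segments entries")
        if self.cell_diameter >= min(self.segment_diameters):
            raise ValueError("cell_diameter must be below the smallest segment diameter")
        if self.duration < 30.0:
            raise ValueError("duration must be >= 30 s so the adhesion rule is exercisable")
        if self.frame_interval <= 0 or self.adherent_jitter < 0:
            raise ValueError("frame_interval must be positive and jitter >= 0")
        unknown = set(self.n_cells_per_class) - {"free", "rolling", "adherent", "transmigrating"}
        if unknown:
            raise ValueError(f"unknown trajectory classes: {unknown}")


def segment_geometry(config: TrajSimConfig) -> list[VesselSegment]:
    """The simulated network: centerline velocity v_max, shear 4 v_max / d."""
    return [
        VesselSegment(
            segment_id=f"S{i + 1}",
            diameter=d,
            v_cc=v,
            shear_rate=4.0 * v / d,
        )
        for i, (d, v) in enumerate(zip(config.segment_diameters, config.v_max_per_segment))
    ]


def generate_trajectories(
    config: TrajSimConfig,
) -> tuple[pd.DataFrame, list[VesselSegment], SimTruth]:
    """Simulate tracked cells of the four known classes.

    Returns the trajectory table (``cell_id, t_s, x_um, y_um,
    segment_id, region``), the vessel geometry, and the truth sidecar
    mapping cell ids to intended labels (``transmigrating`` cells are
    labelled ``transmigrated``, the classifier's vocabulary).
    """
    rng = np.random.default_rng(config.seed)
    segments = segment_geometry(config)
    t = np.arange(0.0, config.duration + config.frame_interval / 2, config.frame_interval)

    records: list[pd.DataFrame] = []
    labels: dict[str, str] = {}
    counter = 0

    def new_cell(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:03d}"

    class_order = ("free", "rolling", "adherent", "transmigrating")
    for cls in class_order:
        n_cls = int(config.n_cells_per_class.get(cls, 0))
        for i in range(n_cls):
            seg = segments[i % config.n_segments]  # round-robin: every segment covered
            Rv = seg.diameter / 2.0
            v_crit = critical_velocity(seg.v_cc, config.cell_diameter, seg.diameter)
            cell_id = new_cell(cls[0].upper())
            x0 = rng.uniform(0.0, 50.0)
            region = np.full(t.shape, "vascular", dtype=object)

            if cls == "free":
                # radius where the parabolic profile clears 1.2 x v_crit
                kappa = v_crit / seg.v_cc  # = eps(2 - eps) < 1
                u_max = np.sqrt(max(1.0 - 1.2 * kappa, 0.0))
                u = rng.uniform(0.0, 0.95 * u_max)
                speed = seg.v_cc * (1.0 - u * u)
                y = np.full_like(t, u * Rv * rng.choice([-1.0, 1.0]))
                x = x0 + speed * t
            elif cls == "rolling":
                speed = rng.uniform(0.05, 0.8) * v_crit
                y = np.full_like(t, (Rv - config.cell_diameter / 2.0))
                x = x0 + speed * t  # monotone crawl along the wall
            elif cls == "adherent":
                half = config.adherent_jitter / 2.0
                x = x0 + rng.uniform(-half, half, t.shape)
                y = (Rv - config.cell_diameter / 2.0) + rng.uniform(-half, half, t.shape)
            else:  # transmigrating: roll, then cross the barrier into tissue
                t_cross = rng.uniform(0.3, 0.7) * config.duration
                speed = rng.uniform(0.05, 0.8) * v_crit
                x = x0 + speed * np.minimum(t, t_cross)
                y = np.full_like(t, (Rv - config.cell_diameter / 2.0))
                after = t >= t_cross
                y = y + np.where(after, 2.0 * (t - t_cross).clip(min=0.0), 0.0)
                idx = int(after.argmax())
                region[after] = "tissue"
                region[idx] = "barrier"  # one frame in the endothelial barrier

            records.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_id,
                        "t_s": t,
                        "x_um": x,
                        "y_um": y,
                        "segment_id": seg.segment_id,
                        "region": region,
                    }
                )
            )
            labels[cell_id] = "transmigrated" if cls == "transmigrating" else cls

    traj = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["cell_id", "t_s", "x_um", "y_um", "segment_id", "region"]
    )
    truth = SimTruth(cell_labels=pd.Series(labels, name="cls"))
    return traj, segments, truth


def generate_dose_cohorts(
    config: TrajSimConfig,
    doses_ng_ml: Sequence[float],
    transmigration_multipliers: Sequence[float],
    n_injected: int = 120,
    baseline_transmigration_prob: float = 0.3,
    seed: int = 0,
) -> dict[float, tuple[pd.DataFrame, list[VesselSegment], SimTruth]]:
    """One trajectory cohort per treatment dose with scaled transmigration.

    Each cohort injects ``n_injected`` cells; the number transmigrating
    is Binomial(n_injected - rolling - adherent, baseline_prob x
    multiplier) with the rolling and adherent counts held at the base
    config's values, and the remainder flowing freely.  Dose 0 should
    carry multiplier 1.0 (the untreated referent).
    """
    if len(doses_ng_ml) != len(transmigration_multipliers):
        raise ValueError("one multiplier per dose required")
    rng = np.random.default_rng(seed)
    n_roll = int(config.n_cells_per_class.get("rolling", 10))
    n_adh = int(config.n_cells_per_class.get("adherent", 10))
    n_pool = n_injected - n_roll - n_adh
    if n_pool <= 0:
        raise ValueError("n_injected too small for the fixed rolling/adherent counts")

    cohorts = {}
    for dose, mult in zip(doses_ng_ml, transmigration_multipliers):
        p = baseline_transmigration_prob * mult
        if not 0 <= p <= 1:
            raise ValueError("transmigration probability outside [0, 1]")
        n_trans = int(rng.binomial(n_pool, p))
        cfg = TrajSimConfig(
            n_segments=config.n_segments,
            segment_diameters=config.segment_diameters,
            v_max_per_segment=config.v_max_per_segment,
            cell_diameter=config.cell_diameter,
            frame_interval=config.frame_interval,
            duration=config.duration,
            n_cells_per_class={
                "free": n_pool - n_trans,
                "rolling": n_roll,
                "adherent": n_adh,
                "transmigrating": n_trans,
            },
            adherent_jitter=config.adherent_jitter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohorts[float(dose)] = generate_trajectories(cfg)
    return cohorts
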