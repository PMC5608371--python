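"""End-to-end screen runner: normalize, collapse, compare, enrich.

``run_screen`` wires the stages together and writes every stage output
plus a machine-readable manifest (parameters, seed, input hashes) so a
run can be reproduced exactly.  Outputs are deterministic: rerunning
with the same config yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import comparisons as cmp
from . import enrichment as enr
from . import io as nio
from .expression import collapse_to_genes, quantile_normalize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full screen run."""

    matrix_path: Path
    design_path: Path
    output_dir: Path
    gmt_path: Path | None = None
    fc_threshold: float = 2.0
    alpha: float = 0.05
    heatmap_referent: tuple[str, str] = ("resistant", "diabetic")
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or not (0.0 < self.alpha < 1.0):
            raise ValueError("fc_threshold must be positive and alpha in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_screen(config: RunConfig) -> dict:
    """Run the four-comparison screen and write all stage outputs.

    Returns a summary dict (also written as ``manifest.json``) with the
    screen counts, exclusive-set sizes and output paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = nio.read_matrix(config.matrix_path, config.design_path)
    logger.info("loaded %d probes x %d samples", *matrix.values.shape)

    normalized = quantile_normalize(matrix)
    collapsed = collapse_to_genes(normalized)
    quad = cmp.run_four_comparisons(collapsed, config.fc_threshold, config.alpha)
    sets = cmp.exclusive_sets(quad)

    for name in ("susceptible_dm", "resistant_dm", "strain_ctrl", "strain_dm"):
        nio.write_de_table(quad[name], out / f"de_{name}.tsv")
    cmp.exclusive_table(quad, sets).to_csv(out / "exclusive_genes.tsv", sep="\t")

    heat = cmp.heatmap_matrix(
        collapsed,
        sets.all_genes,
        referent_group=config.heatmap_referent,
        order_by=quad.strain_dm["fold_change"],
    )
    heat.to_csv(out / "heatmap_log2ratio.tsv", sep="\t")

    enrich_written = None
    if config.gmt_path is not None and sets.all_genes:
        db = enr.read_gmt(config.gmt_path, universe=collapsed.values.index)
        report = enr.enrich_genelist(sets.all_genes, db)
        report.to_csv(out / "enrichment.tsv", sep="\t")
        enrich_written = "enrichment.tsv"

    manifest = {
        "parameters": {
            "fc_threshold": config.fc_threshold,
            "alpha": config.alpha,
            "heatmap_referent": list(config.heatmap_referent),
            "seed": config.seed,
            **config.extra,
        },
        "inputs": {
            "matrix": {"path": str(config.matrix_path), "sha256": _sha256(config.matrix_path)},
            "design": {"path": str(config.design_path), "sha256": _sha256(config.design_path)},
            **(
                {"gmt": {"path": str(config.gmt_path), "sha256": _sha256(config.gmt_path)}}
                if config.gmt_path is not None
                else {}
            ),
        },
        "screen_counts": {
            name: row.to_dict() for name, row in quad.counts().iterrows()
        },
        "exclusive_sets": {
            "up": sets.up_exclusive,
            "down": sets.down_exclusive,
        },
        "outputs": sorted(p.name for p in out.glob("*.tsv")) + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
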