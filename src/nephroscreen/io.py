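"""Readers and writers for the pipeline's on-disk formats.

All tabular outputs are tab-separated UTF-8 with a header row.  The
expression format is: first column probe id, second column gene symbol,
remaining columns sample intensities; the companion design file maps
sample id to strain (susceptible/resistant) and treatment
(control/diabetic).  GEO series-matrix files (metadata lines starting
with ``!``) are supported with a user-supplied YAML mapping sample
titles or accessions to the design vocabulary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.request import urlretrieve

import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .kinetics import VesselSegment

logger = logging.getLogger(__name__)

GEO_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{prefix}nnn/{accession}/matrix/"
    "{accession}_series_matrix.txt.gz"
)


# ----------------------------------------------------------------------
# expression matrix + design
# ----------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.to_csv(path, sep="\t", index_label="probe_id")


def write_design(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.design.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    table = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if "gene_symbol" not in table.columns:
        raise ValueError("expected a 'gene_symbol' second column")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return ExpressionMatrix(
        table.drop(columns="gene_symbol"), table["gene_symbol"], design
    )


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write a screen result with the canonical column subset."""
    cols = ["fold_change", "log2_fc", "p_raw", "p_adj", "direction"]
    de[cols].to_csv(path, sep="\t", index_label="gene")


# ----------------------------------------------------------------------
# GEO series-matrix dialect
# ----------------------------------------------------------------------

def read_series_matrix(
    path: str | Path, design_yaml: str | Path
) -> ExpressionMatrix:
    """Parse a GEO series-matrix file into an ExpressionMatrix.

    Metadata lines beginning with ``!`` are scanned for sample titles
    and accessions; the intensity block between ``!series_matrix_table_begin``
    and ``!series_matrix_table_end`` is read as tab-separated.  The
    ``design_yaml`` file maps each sample (by title or accession) to
    ``{strain: susceptible|resistant, treatment: control|diabetic}``;
    optional key ``gene_symbol_column`` is unused here (symbols must be
    attached separately via a platform annotation if needed, otherwise
    probe ids double as symbols).
    """
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    titles: list[str] = []
    accessions: list[str] = []
    data_lines: list[str] = []
    in_table = False
    with opener(path, "rt", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if line.startswith("!"):
                fields = [f.strip('"') for f in line.split("\t")]
                if fields[0] == "!Sample_title":
                    titles = fields[1:]
                elif fields[0] == "!Sample_geo_accession":
                    accessions = fields[1:]
                continue
            if in_table:
                if "\t" not in line:
                    raise ValueError(f"malformed series-matrix table at line {lineno}")
                data_lines.append(line)

    if not data_lines:
        raise ValueError("no expression table found between table_begin/table_end")
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(data_lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [c.strip('"') for c in table.columns]

    mapping = yaml.safe_load(Path(design_yaml).read_text())
    samples = mapping.get("samples", mapping)
    by_title = dict(zip(titles, table.columns)) if titles else {}
    rows = {}
    for key, grp in samples.items():
        col = key if key in table.columns else by_title.get(key)
        if col is None:
            raise ValueError(f"design entry {key!r} matches no sample column or title")
        rows[col] = {"strain": grp["strain"], "treatment": grp["treatment"]}
    design = pd.DataFrame.from_dict(rows, orient="index")
    design.index.name = "sample_id"

    values = table[list(design.index)].clip(lower=0.0)
    symbols = pd.Series(values.index, index=values.index)
    logger.info("parsed %d probes x %d samples", *values.shape)
    return ExpressionMatrix(values, symbols, design)


def fetch_accession(
    accession: str, cache_dir: str | Path, design_yaml: str | Path
) -> ExpressionMatrix:
    """Download (or reuse a cached copy of) a GEO series matrix.

    Never required by the test suite; a cached file named
    ``<accession>_series_matrix.txt[.gz]`` in ``cache_dir`` short-circuits
    all network access.
    """
    if not accession.startswith("GSE") or not accession[3:].isdigit():
        raise ValueError(f"malformed accession id {accession!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    for suffix in (".txt", ".txt.gz"):
        cached = cache_dir / f"{accession}_series_matrix{suffix}"
        if cached.exists():
            logger.info("using cached %s", cached)
            return read_series_matrix(cached, design_yaml)
    url = GEO_MATRIX_URL.format(prefix=accession[: len(accession) - 3], accession=accession)
    target = cache_dir / f"{accession}_series_matrix.txt.gz"
    try:
        urlretrieve(url, target)
    except Exception as exc:  # noqa: BLE001 - network errors vary widely
        raise RuntimeError(
            f"could not download {url}: {exc}; place the series matrix in "
            f"{cache_dir} manually to run offline"
        ) from exc
    return read_series_matrix(target, design_yaml)


# ----------------------------------------------------------------------
# trajectories + geometry
# ----------------------------------------------------------------------

def write_trajectories(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    traj = pd.read_csv(path)
    required = {"cell_id", "t_s", "x_um", "y_um", "segment_id", "region"}
    missing = required - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    bad_regions = set(traj["region"].unique()) - {"vascular", "barrier", "tissue"}
    if bad_regions:
        raise ValueError(f"unknown region labels: {sorted(bad_regions)}")
    return traj


def write_geometry(segments: list[VesselSegment], path: str | Path) -> None:
    payload = {
        "segments": [
            {
                "segment_id": s.segment_id,
                "diameter_um": s.diameter,
                **({"v_cc_um_s": s.v_cc} if s.v_cc is not None else {}),
                **({"shear_s": s.shear_rate} if s.shear_rate is not None else {}),
            }
            for s in segments
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_geometry(path: str | Path) -> list[VesselSegment]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        VesselSegment(
            segment_id=str(entry["segment_id"]),
            diameter=float(entry["diameter_um"]),
            v_cc=float(entry["v_cc_um_s"]) if "v_cc_um_s" in entry else None,
            shear_rate=float(entry["shear_s"]) if "shear_s" in entry else None,
        )
        for entry in payload["segments"]
    ]
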