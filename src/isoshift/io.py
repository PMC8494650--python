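"""Reading and writing the pipeline's on-disk formats.

Matrices travel as Matrix Market ``.mtx`` with ``barcodes.tsv`` and
``features.tsv`` sidecars (kallisto/bustools layout, cells in rows);
annotation, cell, spatial and marker tables are plain TSV; planted truth
and equivalence-class maps are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import ExpressionMatrix, validate_annotation, validate_cells


def write_mtx(m: ExpressionMatrix, outdir, prefix: str = "") -> None:
    """Write matrix.mtx + barcodes.tsv + features.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / f"{prefix}matrix.mtx", sp.coo_matrix(m.values))
    pd.Series(m.cell_ids).to_csv(outdir / f"{prefix}barcodes.tsv", sep="\t",
                                 index=False, header=False)
    pd.Series(m.feature_ids).to_csv(outdir / f"{prefix}features.tsv", sep="\t",
                                    index=False, header=False)


def read_mtx(
    matrix_path, barcodes_path, features_path,
    feature_level: str = "isoform", state: str = "raw_counts",
) -> ExpressionMatrix:
    values = sp.csr_matrix(sio.mmread(matrix_path))
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
    feats = pd.read_csv(features_path, sep="\t", header=None)[0]
    return ExpressionMatrix(values, pd.Index(cells), pd.Index(feats),
                            feature_level=feature_level, state=state)


def read_mtx_dir(indir, prefix: str = "", **kwargs) -> ExpressionMatrix:
    indir = Path(indir)
    return read_mtx(indir / f"{prefix}matrix.mtx", indir / f"{prefix}barcodes.tsv",
                    indir / f"{prefix}features.tsv", **kwargs)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.reset_index().to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.reset_index().to_csv(path, sep="\t", index=False)


def read_cells(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path, sep="\t"))


def write_spatial(spatial: pd.DataFrame, path) -> None:
    spatial.to_csv(path, sep="\t", index=False)


def read_spatial(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "slice_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spatial table missing columns: {sorted(missing)}")
    return df


def write_ec_map(ec_map: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        json.dump(ec_map, fh, indent=0)


def read_ec_map(path) -> dict[str, list[str]]:
    with open(path) as fh:
        return {k: list(v) for k, v in json.load(fh).items()}
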