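"""Readers and writers for the interchange formats.

Count matrices are accepted either as a MatrixMarket triplet (``matrix.mtx``
plus one-column ``features.tsv`` / ``barcodes.tsv`` name files) or as a dense
TSV with gene rows and a header of spot/cell ids.  Coordinates, annotations,
prediction tables and all result tables are TSV with header rows.  Duplicate
gene symbols are collapsed by summing their rows on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .celltype_pairs import SpotAnnotation, annotate_spots
from .des import PredictionTable
from .tendency import SpatialExpression

__all__ = [
    "read_counts",
    "write_counts",
    "read_coordinates",
    "read_spatial_expression",
    "read_annotation",
    "read_predictions",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def _read_name_file(path: str | Path) -> list[str]:
    frame = pd.read_csv(path, sep="\t", header=None)
    return [str(v) for v in frame.iloc[:, 0]]


def _dedup_rows(matrix: sp.spmatrix | np.ndarray, names: list[str]):
    """Sum rows sharing a gene symbol, keeping first-seen order."""
    if len(set(names)) == len(names):
        return matrix, names
    order: dict[str, int] = {}
    for name in names:
        order.setdefault(name, len(order))
    indicator = sp.csr_matrix(
        (np.ones(len(names)), (np.array([order[n] for n in names]), np.arange(len(names)))),
        shape=(len(order), len(names)),
    )
    summed = indicator @ sp.csr_matrix(matrix)
    logger.info("collapsed %d duplicated gene symbols", len(names) - len(order))
    return summed, list(order)


def read_counts(
    matrix_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
):
    """Read a gene x column count matrix.

    Returns ``(gene_ids, column_ids, matrix)`` with the matrix kept sparse
    for MTX inputs.  For MTX, ``features_path`` and ``barcodes_path`` are
    required and must match the matrix dimensions.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if features_path is None or barcodes_path is None:
            raise FormatError("MTX input requires features and barcodes files")
        matrix = sp.csr_matrix(scipy.io.mmread(matrix_path))
        genes = _read_name_file(features_path)
        cols = _read_name_file(barcodes_path)
        if matrix.shape != (len(genes), len(cols)):
            raise FormatError(
                f"matrix is {matrix.shape} but {len(genes)} features x "
                f"{len(cols)} barcodes were supplied"
            )
    else:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        matrix = frame.to_numpy(dtype=float)
        genes = [str(g) for g in frame.index]
        cols = [str(c) for c in frame.columns]
    if np.prod(matrix.shape) == 0:
        raise FormatError(f"empty count matrix: {matrix_path}")
    matrix, genes = _dedup_rows(matrix, genes)
    return genes, cols, matrix


def write_counts(
    genes: list[str], cols: list[str], matrix, path: str | Path
) -> None:
    """Write a count matrix as dense TSV (gene rows, id header)."""
    dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
    pd.DataFrame(dense, index=genes, columns=cols).to_csv(path, sep="\t")


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read spot coordinates (columns spot_id, x, y)."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"spot_id", "x", "y"} - set(frame.columns)
    if missing:
        raise FormatError(f"coordinates file missing column(s): {sorted(missing)}")
    frame["spot_id"] = frame["spot_id"].astype(str)
    return frame.set_index("spot_id")


def read_spatial_expression(
    counts_path: str | Path,
    coords_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> SpatialExpression:
    """Assemble a :class:`SpatialExpression` from counts plus coordinates.

    Spots are intersected between the two files and ordered as in the
    count matrix; spots lacking coordinates are an error.
    """
    genes, spots, matrix = read_counts(counts_path, features_path, barcodes_path)
    coords = read_coordinates(coords_path)
    missing = [s for s in spots if s not in coords.index]
    if missing:
        raise FormatError(
            f"{len(missing)} spot(s) have counts but no coordinates, "
            f"e.g. {missing[:3]}"
        )
    xy = coords.loc[spots, ["x", "y"]].to_numpy(dtype=float)
    return SpatialExpression(gene_ids=genes, spot_ids=spots, coords=xy, values=matrix)


def read_annotation(path: str | Path) -> SpotAnnotation:
    """Read spot annotation: either hard labels or a proportions table.

    A file with columns ``spot_id, cell_type`` is taken as hard labels;
    otherwise every non-``spot_id`` column is treated as a cell-type
    proportion and spots are labeled by argmax.
    """
    frame = pd.read_csv(path, sep="\t")
    if "spot_id" not in frame.columns:
        raise FormatError("annotation file must have a spot_id column")
    frame["spot_id"] = frame["spot_id"].astype(str)
    frame = frame.set_index("spot_id")
    if list(frame.columns) == ["cell_type"]:
        return SpotAnnotation(
            spot_ids=[str(s) for s in frame.index],
            labels=[str(l) for l in frame["cell_type"]],
        )
    return annotate_spots(frame)


def read_predictions(path: str | Path, tool_name: str | None = None) -> PredictionTable:
    """Read one CCI tool's prediction table.

    Expected columns: ``tool, source_celltype, target_celltype, ligand,
    receptor, score, pvalue`` (``tool``, ``score`` and ``pvalue`` optional;
    the tool name falls back to the file stem).
    """
    frame = pd.read_csv(path, sep="\t")
    name = tool_name or (
        str(frame["tool"].iloc[0]) if "tool" in frame.columns and len(frame) else Path(path).stem
    )
    frame = frame.drop(columns=[c for c in ("tool",) if c in frame.columns])
    return PredictionTable(tool_name=name, records=frame)
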