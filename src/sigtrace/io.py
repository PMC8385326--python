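"""Reading and writing of fixtures: MTX + TSV single-cell bundles,
bulk counts/metadata TSVs, ground-truth JSON and GMT gene sets."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BulkStudy, CellMatrix, META_COLUMNS, SignatureSet
from .simdata import GroundTruth

__all__ = [
    "write_fixture",
    "read_cell_matrix",
    "read_bulk_study",
    "read_ground_truth",
    "read_gmt",
    "write_gmt",
]


def write_fixture(dataset, directory) -> list[Path]:
    """Write a dataset (CellMatrix, BulkStudy, GroundTruth or tuple) to disk.

    Returns the list of files written.  Formats round-trip losslessly via
    the matching ``read_*`` functions.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset, tuple):
        written: list[Path] = []
        for part in dataset:
            written.extend(write_fixture(part, directory))
        return written
    if isinstance(dataset, CellMatrix):
        return _write_cell_matrix(dataset, directory)
    if isinstance(dataset, BulkStudy):
        return _write_bulk_study(dataset, directory)
    if isinstance(dataset, GroundTruth):
        path = directory / "ground_truth.json"
        path.write_text(json.dumps(dataset.to_dict(), indent=1, sort_keys=True))
        return [path]
    raise TypeError(f"cannot write dataset of type {type(dataset).__name__}")


def _write_cell_matrix(matrix: CellMatrix, directory: Path) -> list[Path]:
    mtx = directory / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(matrix.counts.astype(np.int64)))
    barcodes = directory / "barcodes.tsv"
    pd.DataFrame(
        {"barcode": matrix.barcode_ids, "donor": matrix.donor}
    ).to_csv(barcodes, sep="\t", index=False)
    features = directory / "features.tsv"
    pd.DataFrame(
        {"gene_id": matrix.gene_ids, "mito": matrix.mito_flags.astype(int)}
    ).to_csv(features, sep="\t", index=False)
    return [mtx, barcodes, features]


def _write_bulk_study(study: BulkStudy, directory: Path) -> list[Path]:
    counts = directory / "counts.tsv"
    study.counts.rename_axis("gene").to_csv(counts, sep="\t")
    meta = directory / "metadata.tsv"
    out = study.meta.reset_index()[list(META_COLUMNS)]
    out.to_csv(meta, sep="\t", index=False)
    return [counts, meta]


def read_cell_matrix(directory) -> CellMatrix:
    """Read a matrix.mtx + barcodes.tsv + features.tsv bundle."""
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", dtype=str)
    features = pd.read_csv(directory / "features.tsv", sep="\t")
    return CellMatrix(
        counts=counts.astype(np.int64),
        gene_ids=features["gene_id"].astype(str).tolist(),
        barcode_ids=barcodes["barcode"].tolist(),
        mito_flags=features["mito"].astype(int).to_numpy().astype(bool),
        donor=barcodes["donor"].to_numpy(dtype=object),
    )


def read_bulk_study(directory) -> BulkStudy:
    """Read a counts.tsv + metadata.tsv bundle."""
    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", dtype=str)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.tsv is missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    return BulkStudy(counts=counts, meta=meta)


def read_ground_truth(directory) -> GroundTruth:
    directory = Path(directory)
    data = json.loads((directory / "ground_truth.json").read_text())
    return GroundTruth.from_dict(data)


def read_gmt(path) -> SignatureSet:
    """Read GMT gene sets (name, description, genes...).

    Malformed lines raise ``ValueError`` with the line number; duplicate
    genes within a line are removed with a warning.
    """
    sigs = SignatureSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least name and "
                    "description fields"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g != ""]
            if name in sigs.sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set '{name}'")
            sigs.add(name, genes)
    return sigs


def write_gmt(signatures: SignatureSet, path) -> Path:
    """Write signatures as GMT, one line per set, preserving gene order."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in signatures:
            genes = signatures.genes(name)
            fh.write("\t".join([name, f"n={len(genes)}", *genes]) + "\n")
    return path
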