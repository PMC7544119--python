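"""Readers and writers for expression matrices, annotation and atlas models.

Expression files are genes-in-rows, samples-in-columns, first column =
gene id (the common GEO series-matrix layout); ``orient="samples"`` flips.
10x-style directories (matrix.mtx + features/genes.tsv + barcodes.tsv) are
read through scipy's MatrixMarket support with zeros kept exact.  A fitted
atlas is stored as a directory of plain-text tables plus a JSON config, so
every artefact is human-inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import ANNOTATION_REQUIRED_COLUMNS, AtlasModel, ExpressionMatrix, SampleAnnotation

__all__ = ["read_expression", "read_annotation", "save_atlas", "load_atlas"]

_ATLAS_FILES = ("config.json", "genes.tsv", "gene_means.tsv", "loadings.tsv", "coords.tsv")


def _read_delimited(path: Path, sep: str, orient: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if orient == "samples":
        df = df.T
    return df


def read_expression(path, format: str | None = None, orient: str = "genes") -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or a 10x-style MTX directory.

    ``format`` is one of ``tsv``, ``csv`` or ``mtx_dir``; inferred from the
    path when omitted.  ``orient="genes"`` (default) expects genes in rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"
    if format == "tsv":
        df = _read_delimited(path, "\t", orient)
    elif format == "csv":
        df = _read_delimited(path, ",", orient)
    elif format == "mtx_dir":
        df = _read_mtx_dir(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return ExpressionMatrix(df, value_kind="raw")


def _read_mtx_dir(path: Path) -> pd.DataFrame:
    mtx = next((path / n for n in ("matrix.mtx", "matrix.mtx.gz") if (path / n).exists()), None)
    feats = next(
        (path / n for n in ("features.tsv", "genes.tsv") if (path / n).exists()), None
    )
    barcodes = path / "barcodes.tsv"
    missing = [
        name
        for name, p in [("matrix.mtx", mtx), ("features.tsv/genes.tsv", feats),
                        ("barcodes.tsv", barcodes if barcodes.exists() else None)]
        if p is None
    ]
    if missing:
        raise FileNotFoundError(f"MTX directory {path} is missing: {missing}")
    mat = scipy.io.mmread(mtx)
    features = pd.read_csv(feats, sep="\t", header=None)
    genes = features.iloc[:, 0].astype(str).tolist()
    cells = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} features x {len(cells)} barcodes"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene_id")


def read_annotation(path) -> SampleAnnotation:
    """Read a sample annotation table (CSV or TSV, by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in ANNOTATION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} missing mandatory column(s): {missing}")
    return SampleAnnotation(df)


def save_atlas(model: AtlasModel, dirpath) -> None:
    """Serialise a fitted atlas into a directory of plain-text tables."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    cfg = {
        "threshold": model.threshold,
        "n_components": model.n_components,
        "n_selected_genes": len(model.selected_genes),
        "explained_variance": model.explained_variance.tolist(),
        "provenance": model.provenance,
    }
    (d / "config.json").write_text(json.dumps(cfg, indent=2))
    pd.Series(model.selected_genes, name="gene_id").to_csv(
        d / "genes.tsv", sep="\t", index=False
    )
    model.gene_means.rename("mean_percentile").to_csv(
        d / "gene_means.tsv", sep="\t", index_label="gene_id", float_format="%.17g"
    )
    pd.DataFrame(
        model.loadings, index=model.component_names, columns=model.selected_genes
    ).to_csv(d / "loadings.tsv", sep="\t", index_label="component", float_format="%.17g")
    model.training_coords.to_csv(
        d / "coords.tsv", sep="\t", index_label="sample_id", float_format="%.17g"
    )


def load_atlas(dirpath) -> AtlasModel:
    """Load an atlas saved by :func:`save_atlas`."""
    d = Path(dirpath)
    for name in _ATLAS_FILES:
        if not (d / name).exists():
            raise FileNotFoundError(f"atlas directory {d} is missing {name}")
    cfg = json.loads((d / "config.json").read_text())
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    means = pd.read_csv(d / "gene_means.tsv", sep="\t", index_col="gene_id")[
        "mean_percentile"
    ]
    means.index = means.index.astype(str)
    loadings = pd.read_csv(d / "loadings.tsv", sep="\t", index_col="component")
    coords = pd.read_csv(d / "coords.tsv", sep="\t", index_col="sample_id")
    return AtlasModel(
        selected_genes=genes,
        gene_means=means.reindex(genes),
        loadings=loadings[genes].to_numpy(),
        explained_variance=np.asarray(cfg["explained_variance"], dtype=float),
        training_coords=coords,
        threshold=float(cfg["threshold"]),
        n_components=int(cfg["n_components"]),
        provenance=cfg.get("provenance", {}),
    )
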