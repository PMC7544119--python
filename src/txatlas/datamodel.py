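"""Core containers for expression data, sample annotation and fitted atlases.

The containers are thin, validated wrappers around pandas objects.  An
:class:`ExpressionMatrix` is always genes-in-rows, samples-in-columns; the
``value_kind`` field distinguishes raw abundances (RPKM, microarray
intensity, counts) from rank-percentile values on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "AtlasModel",
    "ANNOTATION_REQUIRED_COLUMNS",
    "ANNOTATION_OPTIONAL_COLUMNS",
]

ANNOTATION_REQUIRED_COLUMNS = ("sample_id", "dataset_id", "platform")
ANNOTATION_OPTIONAL_COLUMNS = ("cell_type", "progenitor_type", "sample_source")

SAMPLE_SOURCE_LEVELS = ("in_vivo", "ex_vivo", "in_vitro")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns.
    value_kind : {"raw", "percentile"}
        ``"percentile"`` asserts all values lie in [0, 1].
    """

    values: pd.DataFrame
    value_kind: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.value_kind not in ("raw", "percentile"):
            raise ValueError(f"value_kind must be 'raw' or 'percentile', got {self.value_kind!r}")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.value_kind == "percentile":
            arr = self.values.to_numpy()
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValueError("percentile values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples-in-rows orientation used by the estimator layer."""
        return self.values.T

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.value_kind)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown gene ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.value_kind)


@dataclass
class SampleAnnotation:
    """Per-sample metadata table.

    Mandatory columns: ``sample_id``, ``dataset_id``, ``platform``.
    Optional: ``cell_type``, ``progenitor_type``, ``sample_source``
    (one of in_vivo / ex_vivo / in_vitro).  Missing optional columns are
    created as all-null so downstream code can rely on their presence.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in ANNOTATION_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing mandatory column(s): {missing}")
        _check_unique(df["sample_id"], "sample ids")
        for col in ANNOTATION_OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series([None] * len(df), dtype=object)
        df["sample_id"] = df["sample_id"].astype(str)
        bad = df["sample_source"].dropna()
        bad = bad[~bad.isin(SAMPLE_SOURCE_LEVELS)]
        if len(bad):
            raise ValueError(
                f"sample_source values must be one of {SAMPLE_SOURCE_LEVELS}; got {bad.unique().tolist()[:5]}"
            )
        used = df["platform"].isna() | (df["platform"].astype(str) == "") \
            | df["dataset_id"].isna() | (df["dataset_id"].astype(str) == "")
        if used.any():
            raise ValueError("platform and dataset_id must be non-empty for every sample")
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def platform_of(self, sample_ids) -> pd.Series:
        return self.df.loc[list(sample_ids), "platform"]

    def dataset_of(self, sample_ids) -> pd.Series:
        return self.df.loc[list(sample_ids), "dataset_id"]

    def class_of(self, sample_ids, class_field: str) -> pd.Series:
        if class_field not in ("cell_type", "progenitor_type", "sample_source"):
            raise ValueError(f"unknown class field {class_field!r}")
        return self.df.loc[list(sample_ids), class_field]

    def subset(self, sample_ids) -> "SampleAnnotation":
        missing = set(map(str, sample_ids)) - set(self.df.index)
        if missing:
            raise KeyError(f"unknown sample ids in annotation: {sorted(missing)[:5]}")
        return SampleAnnotation(self.df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class AtlasModel:
    """A fitted PCA reference atlas.

    Stores everything required to reproduce training coordinates and to
    project new samples without refitting: the platform-robust gene list,
    per-gene training means of the percentile values, orthonormal PCA
    loadings (components x genes), per-component explained variances and
    the coordinates of the training samples.
    """

    selected_genes: list[str]
    gene_means: pd.Series            # indexed by selected_genes
    loadings: np.ndarray             # (n_components, n_genes)
    explained_variance: np.ndarray   # (n_components,)
    training_coords: pd.DataFrame    # samples x components, cols PC1..PCn
    threshold: float
    n_components: int
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        k, g = self.loadings.shape
        if k != self.n_components:
            raise ValueError("loadings row count must equal n_components")
        if g != len(self.selected_genes):
            raise ValueError("loadings column count must equal number of selected genes")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("loading rows must be unit-norm")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]

    def transform_percentiles(self, pct: pd.DataFrame) -> np.ndarray:
        """Map samples x selected-genes percentile data into atlas coordinates."""
        centered = pct[self.selected_genes].to_numpy() - self.gene_means.to_numpy()
        return centered @ self.loadings.T
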