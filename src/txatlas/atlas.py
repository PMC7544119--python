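"""Atlas construction: gene filtering on platform variance, then PCA.

The central estimator is :class:`AtlasPCA`, a scikit-learn transformer.
Fitting (i) partitions each gene's variance into platform and residual
parts with a fixed-effect ANOVA, (ii) keeps genes whose platform fraction
is strictly below the threshold (default 0.2), and (iii) fits a PCA on the
retained percentile values, centring each gene on its training mean with no
variance scaling.  Transforming maps percentile data for the selected genes
into atlas coordinates.

Recursive refinement (:func:`build_subatlas`) re-runs the whole pipeline —
variance partitioning, selection and PCA — on a sample subset, because the
informative gene set is resolution-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .datamodel import AtlasModel, ExpressionMatrix, SampleAnnotation
from .variance import platform_variance_fraction, platform_variance_fraction_frame

__all__ = [
    "BuildConfig",
    "AtlasPCA",
    "common_gene_universe",
    "select_genes",
    "fit_atlas",
    "build_subatlas",
    "component_platform_dependence",
]


@dataclass
class BuildConfig:
    """Parameters of an atlas build.

    threshold : platform-variance fraction below which a gene is kept.
    n_components : number of PCA components retained (first 3 are the
        display coordinates).
    common_genes_only : restrict to genes present on every platform before
        ranking.
    seed : random seed recorded in provenance (the build itself is
        deterministic up to the fixed sign convention).
    """

    threshold: float = 0.2
    n_components: int = 10
    common_genes_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _flip_signs(components: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-magnitude loading entry positive
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None], coords * signs[None, :]


class AtlasPCA(BaseEstimator, TransformerMixin):
    """Platform-variance gene filter followed by PCA.

    Parameters
    ----------
    threshold : float, default=0.2
        Genes with platform variance fraction strictly below this are kept.
    n_components : int, default=10
        Components retained.
    random_state : int, default=0
        Recorded for provenance; the fit is deterministic.

    Attributes
    ----------
    variance_table_ : per-gene ANOVA decomposition of the training data.
    selected_genes_ : genes passing the filter, input order preserved.
    gene_means_ : training mean percentile of each selected gene.
    components_ : (n_components, n_selected) orthonormal loadings.
    explained_variance_ : per-component variances, non-increasing.
    training_coords_ : (n_samples, n_components) training coordinates.
    """

    def __init__(self, threshold: float = 0.2, n_components: int = 10, random_state: int = 0):
        self.threshold = threshold
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None, *, platform=None):
        """Fit on samples x genes percentile data.

        ``platform`` gives the per-sample platform label; for pipeline
        compatibility it may also be passed as ``y``.
        """
        if platform is None:
            platform = y
        if platform is None:
            raise ValueError("platform labels are required to fit an atlas")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        X = pd.DataFrame(X)
        X.columns = X.columns.astype(str)
        arr = X.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("AtlasPCA expects rank-percentile values in [0, 1]")
        if self.n_components > min(X.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_samples, n_genes)={min(X.shape)}"
            )
        self.variance_table_ = platform_variance_fraction_frame(X.T, platform)
        self.selected_genes_ = select_genes(self.variance_table_, self.threshold)
        sub = X[self.selected_genes_]
        if self.n_components > min(sub.shape):
            raise ValueError(
                f"only {sub.shape[1]} genes pass the {self.threshold} threshold; "
                f"cannot fit {self.n_components} components"
            )
        self.gene_means_ = sub.mean(axis=0)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        coords = pca.fit_transform(sub.to_numpy() - self.gene_means_.to_numpy())
        self.components_, self.training_coords_ = _flip_signs(pca.components_, coords)
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.training_index_ = X.index
        return self

    def transform(self, X):
        """Project samples x genes percentile data into atlas coordinates.

        ``X`` must contain every selected gene (as DataFrame columns, or as
        an array with the same column layout as the fit data).  Missing-gene
        handling for external data lives in :func:`txatlas.projection.project`.
        """
        check_is_fitted(self, "components_")
        if isinstance(X, pd.DataFrame):
            X = X.copy()
            X.columns = X.columns.astype(str)
            missing = [g for g in self.selected_genes_ if g not in X.columns]
            if missing:
                raise KeyError(f"selected genes absent from input: {missing[:5]}")
            sub = X[self.selected_genes_].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != self.n_features_in_:
                raise ValueError("array input must have the same columns as the fit data")
            cols = pd.Index(self.feature_names_in_)
            sub = X[:, cols.get_indexer(self.selected_genes_)]
        return (sub - self.gene_means_.to_numpy()) @ self.components_.T

    def to_model(self, provenance: dict | None = None) -> AtlasModel:
        check_is_fitted(self, "components_")
        coords = pd.DataFrame(
            self.training_coords_,
            index=self.training_index_,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        return AtlasModel(
            selected_genes=list(self.selected_genes_),
            gene_means=self.gene_means_.copy(),
            loadings=self.components_.copy(),
            explained_variance=self.explained_variance_.copy(),
            training_coords=coords,
            threshold=self.threshold,
            n_components=self.n_components,
            provenance=dict(provenance or {}),
        )


def common_gene_universe(matrices: list[ExpressionMatrix], platform_of: dict) -> list[str]:
    """Genes measurable on every platform, sorted.

    ``platform_of`` maps each matrix's position (or any hashable key used
    consistently) to a platform name; genes measurable on a platform are
    the union over that platform's matrices.
    """
    per_platform: dict[str, set[str]] = {}
    for i, m in enumerate(matrices):
        plat = platform_of[i] if i in platform_of else platform_of[m]
        per_platform.setdefault(plat, set()).update(m.gene_ids)
    if not per_platform:
        raise ValueError("no matrices supplied")
    common = set.intersection(*per_platform.values())
    if not common:
        raise ValueError("no genes are measurable on all platforms")
    return sorted(common)


def select_genes(genevar: pd.DataFrame, threshold: float) -> list[str]:
    """Genes with platform variance fraction strictly below the threshold.

    Input order is preserved.  Raises when nothing passes (advising a
    larger threshold) so downstream PCA never sees an empty gene set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    mask = genevar["fraction_platform"].to_numpy() < threshold
    selected = genevar.index[mask].tolist()
    if not selected:
        raise ValueError(
            f"no genes pass the platform-variance threshold {threshold}; try a larger threshold"
        )
    return selected


def fit_atlas(
    percentiles: ExpressionMatrix, annot: SampleAnnotation, cfg: BuildConfig | None = None
) -> AtlasModel:
    """Build a PCA atlas from rank-percentile data and sample annotation."""
    cfg = cfg or BuildConfig()
    if percentiles.value_kind != "percentile":
        raise ValueError("fit_atlas expects rank-percentile values; run rank_percentile first")
    if percentiles.n_samples < cfg.n_components:
        raise ValueError(
            f"{percentiles.n_samples} samples cannot support {cfg.n_components} components"
        )
    est = AtlasPCA(threshold=cfg.threshold, n_components=cfg.n_components)
    est.fit(
        percentiles.to_samples_by_genes(),
        platform=annot.platform_of(percentiles.sample_ids).to_numpy(),
    )
    provenance = {
        "threshold": cfg.threshold,
        "n_components": cfg.n_components,
        "common_genes_only": cfg.common_genes_only,
        "seed": cfg.seed,
        "n_training_samples": percentiles.n_samples,
        "n_input_genes": percentiles.n_genes,
    }
    return est.to_model(provenance)


def build_subatlas(
    parent_percentiles: ExpressionMatrix,
    annot: SampleAnnotation,
    sample_subset: list[str],
    cfg: BuildConfig | None = None,
) -> AtlasModel:
    """Recursive refinement: rebuild the atlas from scratch on a sample subset.

    Variance partitioning, gene selection and PCA are all recomputed on the
    subset, so parent and child gene lists generally differ — finer biology
    recruits a different platform-robust gene set.
    """
    if not sample_subset:
        raise ValueError("sample subset is empty")
    sub = parent_percentiles.subset_samples(sample_subset)
    if annot.platform_of(sub.sample_ids).nunique() < 2:
        raise ValueError("platform effect unidentifiable: subset spans a single platform")
    return fit_atlas(sub, annot, cfg)


def component_platform_dependence(
    model: AtlasModel, annot: SampleAnnotation, n_components: int = 10
) -> pd.DataFrame:
    """Kruskal-Wallis H of each component's training scores grouped by platform.

    Lower H means the component depends less on platform.  Platforms with
    fewer than 2 training samples are dropped with a warning.
    """
    n_components = min(n_components, model.n_components)
    plat = annot.platform_of(model.training_coords.index).to_numpy()
    levels, counts = np.unique(plat, return_counts=True)
    small = levels[counts < 2]
    if small.size:
        warnings.warn(
            f"dropping platform(s) with <2 samples from KW diagnostic: {small.tolist()}",
            UserWarning,
            stacklevel=2,
        )
        keep = ~np.isin(plat, small)
        plat = plat[keep]
        coords = model.training_coords.to_numpy()[keep]
        levels = levels[counts >= 2]
    else:
        coords = model.training_coords.to_numpy()
    if levels.size < 2:
        raise ValueError("need at least 2 platforms with >=2 samples")
    rows = []
    for c in range(n_components):
        groups = [coords[plat == lv, c] for lv in levels]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                h, _ = kruskal(*groups)
            if not np.isfinite(h):  # all values tied: no rank variation
                h = 0.0
        except ValueError:  # scipy rejects fully identical input
            h = 0.0
        rows.append(
            {"component_index": c + 1, "kw_h_statistic": float(h), "n_platforms": len(levels)}
        )
    return pd.DataFrame(rows)
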