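"""Projection of external data onto a fitted atlas.

New samples are rank-percentile transformed (each sample independently,
over its own measured gene set by default), restricted to the atlas gene
list, centred on the atlas training means and multiplied by the stored
loadings — no refitting, so the atlas coordinate system is fixed.  Atlas
genes missing from the projected data receive percentile 0 (the lowest
rank); a large missing fraction distorts the projection and triggers a
warning.

Single cells are not projected individually by default: sparse dropout
makes their rank structure unlike any bulk platform.  Instead
:func:`pseudobulk` sums counts over fixed-size random pools of cells
sharing a cluster identity, and the pools are projected as bulk samples.
An off-atlas score (distance to the nearest training sample in the 3D
display space) flags projections that land far from every populated
region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AtlasModel, ExpressionMatrix
from .rank import rank_percentile_single

__all__ = [
    "ProjectionResult",
    "PseudoBulkConfig",
    "project",
    "pseudobulk",
    "off_atlas_score",
]


@dataclass
class ProjectionResult:
    coords: pd.DataFrame                 # samples x components, cols PC1..PCn
    n_missing_genes: pd.Series           # per sample
    missing_fraction: pd.Series          # per sample, n_missing / |selected_genes|
    off_atlas_score: pd.Series | None = None
    off_atlas_flag: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.coords.index.tolist()


@dataclass
class PseudoBulkConfig:
    """Pseudo-bulk aggregation parameters.

    pool_size : cells summed per aggregate (default 9, within the 8-10
        range that approximates bulk data structure for 10x data).
    drop_remainder : discard leftover cells so every pool has exactly
        ``pool_size`` members.
    """

    pool_size: int = 9
    drop_remainder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def project(
    atlas: AtlasModel,
    expr: ExpressionMatrix,
    rank_over: str = "full",
    missing_warn_fraction: float = 0.5,
    flag: bool = True,
) -> ProjectionResult:
    """Project raw external expression data into atlas coordinates.

    Parameters
    ----------
    atlas : fitted :class:`AtlasModel`.
    expr : raw expression matrix (any units; only ranks are used).
    rank_over : {"full", "atlas"}
        Rank each sample over its full measured gene list (default) or
        only over the atlas genes it shares.
    missing_warn_fraction : warn when a sample is missing more than this
        fraction of the atlas genes.
    flag : also compute the off-atlas score/flag against the training
        coordinates.
    """
    if expr.value_kind != "raw":
        raise ValueError("project expects raw expression values; ranking is applied internally")
    if rank_over not in ("full", "atlas"):
        raise ValueError("rank_over must be 'full' or 'atlas'")
    selected = atlas.selected_genes
    present = [g for g in selected if g in set(expr.gene_ids)]
    if not present:
        raise ValueError("no overlap between the sample's genes and the atlas gene list")

    n_sel = len(selected)
    coords = np.empty((expr.n_samples, atlas.n_components))
    n_missing = np.empty(expr.n_samples, dtype=int)
    gene_means = atlas.gene_means.reindex(selected).to_numpy()
    for j, sid in enumerate(expr.sample_ids):
        col = expr.values.iloc[:, j]
        if rank_over == "atlas":
            col = col.loc[present]
        pct = pd.Series(rank_percentile_single(col.to_numpy()), index=col.index)
        vec = pct.reindex(selected)
        miss = int(vec.isna().sum())
        vec = vec.fillna(0.0).to_numpy()  # absent genes take the lowest rank
        coords[j] = (vec - gene_means) @ atlas.loadings.T
        n_missing[j] = miss

    missing_fraction = pd.Series(n_missing / n_sel, index=expr.sample_ids)
    high = missing_fraction[missing_fraction > missing_warn_fraction]
    if len(high):
        warnings.warn(
            f"{len(high)} sample(s) are missing more than "
            f"{missing_warn_fraction:.0%} of the atlas genes; their projections may be distorted",
            UserWarning,
            stacklevel=2,
        )
    result = ProjectionResult(
        coords=pd.DataFrame(coords, index=expr.sample_ids, columns=atlas.component_names),
        n_missing_genes=pd.Series(n_missing, index=expr.sample_ids),
        missing_fraction=missing_fraction,
    )
    if flag:
        score, flags = off_atlas_score(atlas, result)
        result.off_atlas_score = score
        result.off_atlas_flag = flags
    return result


def pseudobulk(
    cells: ExpressionMatrix,
    cluster_labels: pd.Series,
    cfg: PseudoBulkConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Sum single-cell counts into fixed-size pools within each cluster.

    Within each cluster, cells are randomly partitioned (under the config
    seed) into pools of exactly ``pool_size``; each pool's gene value is
    the sum of its member cells' counts and the pool inherits the cluster
    identity.  Remainder cells are dropped by default so pools are
    equal-sized.  Clusters smaller than ``pool_size`` yield no pools (with
    a warning).

    Returns the pooled expression matrix and a pool annotation frame with
    columns ``pool_id``, ``cluster`` and ``n_cells``.
    """
    cfg = cfg or PseudoBulkConfig()
    labels = pd.Series(cluster_labels)
    labels.index = labels.index.astype(str)
    unlabelled = set(cells.sample_ids) - set(labels.index)
    if unlabelled:
        raise ValueError(f"cells without a cluster label: {sorted(unlabelled)[:5]}")
    arr = cells.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    cols = pd.Index(cells.sample_ids)
    pooled_cols, annot_rows = {}, []
    too_small = []
    for clust in pd.unique(labels.loc[cols]):
        members = [c for c in cols if labels[c] == clust]
        if len(members) < cfg.pool_size:
            too_small.append(clust)
            continue
        order = rng.permutation(len(members))
        n_pools = len(members) // cfg.pool_size
        for p in range(n_pools):
            take = [members[i] for i in order[p * cfg.pool_size:(p + 1) * cfg.pool_size]]
            pool_id = f"{clust}_pool{p + 1}"
            pooled_cols[pool_id] = cells.values[take].sum(axis=1)
            annot_rows.append({"pool_id": pool_id, "cluster": clust, "n_cells": len(take)})
        if not cfg.drop_remainder and len(members) % cfg.pool_size:
            take = [members[i] for i in order[n_pools * cfg.pool_size:]]
            pool_id = f"{clust}_pool{n_pools + 1}"
            pooled_cols[pool_id] = cells.values[take].sum(axis=1)
            annot_rows.append({"pool_id": pool_id, "cluster": clust, "n_cells": len(take)})
    if too_small:
        warnings.warn(
            f"cluster(s) smaller than pool_size={cfg.pool_size} produced no pools: "
            f"{too_small[:5]}",
            UserWarning,
            stacklevel=2,
        )
    if not pooled_cols:
        raise ValueError("no cluster is large enough to form a single pool")
    pools = ExpressionMatrix(pd.DataFrame(pooled_cols, index=cells.values.index), "raw")
    return pools, pd.DataFrame(annot_rows)


def off_atlas_score(
    atlas: AtlasModel,
    result: ProjectionResult,
    n_dims: int | None = None,
    quantile: float = 0.95,
) -> tuple[pd.Series, pd.Series]:
    """Distance to the nearest atlas training sample, with an outlier flag.

    The score is the Euclidean distance (over the first ``n_dims``
    components; all retained components by default) from each projected
    sample to its nearest training sample.  The flag is set when the score
    exceeds the given quantile (default 95th) of the training samples' own
    nearest-neighbour distances — i.e. the sample sits farther from the
    atlas than almost any training sample sits from its neighbours.

    All components are used by default because off-atlas profiles, whose
    cell-type signal is orthogonal to the atlas types, project near the
    centre of the display space; in a crowded 3D view that central region
    may sit close to a populated cluster, while over the full component
    space the distances separate cleanly.
    """
    d = atlas.n_components if n_dims is None else min(n_dims, atlas.n_components)
    train = atlas.training_coords.to_numpy()[:, :d]
    query = result.coords.to_numpy()[:, :d]
    from scipy.spatial.distance import cdist

    dist = cdist(query, train)
    score = dist.min(axis=1)
    train_d = cdist(train, train)
    np.fill_diagonal(train_d, np.inf)
    nn = train_d.min(axis=1)
    cutoff = float(np.quantile(nn, quantile))
    idx = result.coords.index
    return pd.Series(score, index=idx), pd.Series(score > cutoff, index=idx)
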