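"""Cluster stability under resampling.

Atlas coordinates (first 3 components by default) are clustered with
K-means or Ward agglomerative clustering.  Stability is assessed by
re-running the *entire* build pipeline — variance partitioning, gene
selection, PCA, clustering — on resampled data, matching each original
cluster to the resample clustering by maximum Jaccard similarity over the
shared samples, and summarising each cluster's max-Jaccard profile with an
H-index: the largest h in [0, 1] such that a fraction >= h of resamples
achieved Jaccard >= h.  H = 1 iff the cluster is recovered exactly in every
resample.

Two resampling schemes are supported: jackknife (leave-one-dataset-out) and
bootstrap over samples (or datasets) with replacement.  Gene-selection
stability is tracked alongside: the percentage of the full-data gene set
recovered in each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .atlas import AtlasPCA, BuildConfig
from .datamodel import ExpressionMatrix, SampleAnnotation

__all__ = [
    "ClusteringResult",
    "StabilityReport",
    "cluster",
    "jaccard",
    "h_index",
    "resample_stability",
    "select_k",
]


@dataclass
class ClusteringResult:
    algorithm: str
    k: int
    labels: pd.Series  # indexed by sample id
    coords_dim: int

    def members(self, label) -> set[str]:
        return set(self.labels.index[self.labels == label])


@dataclass
class StabilityReport:
    algorithm: str
    k: int
    scheme: str
    per_cluster_h: dict = field(default_factory=dict)
    n_resamples: int = 0
    n_skipped: int = 0
    gene_overlap_pct: list = field(default_factory=list)

    @property
    def median_h(self) -> float:
        return float(np.median(list(self.per_cluster_h.values())))

    @property
    def min_h(self) -> float:
        return float(np.min(list(self.per_cluster_h.values())))

    @property
    def max_h(self) -> float:
        return float(np.max(list(self.per_cluster_h.values())))


def cluster(coords, algorithm: str = "kmeans", k: int = 2, seed: int = 0,
            n_dims: int = 3) -> ClusteringResult:
    """Cluster sample coordinates with K-means or Ward agglomerative.

    ``coords`` is a samples x components DataFrame (atlas training
    coordinates or projections); only the first ``n_dims`` components are
    used, matching the 3D display space the atlas is read in.
    """
    coords = pd.DataFrame(coords)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(coords):
        raise ValueError(f"k={k} exceeds the {len(coords)} samples")
    use = coords.iloc[:, : min(n_dims, coords.shape[1])].to_numpy(dtype=float)
    if algorithm == "kmeans":
        est = KMeans(n_clusters=k, n_init=10, random_state=seed)
    elif algorithm == "agglomerative":
        est = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="ward")
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    labels = est.fit_predict(use)
    return ClusteringResult(
        algorithm=algorithm,
        k=k,
        labels=pd.Series(labels, index=coords.index),
        coords_dim=use.shape[1],
    )


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity |a & b| / |a | b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def h_index(jaccards) -> float:
    """Continuous h-index of a max-Jaccard profile.

    The largest h in [0, 1] such that at least a fraction h of the
    resamples achieved Jaccard >= h.  With values sorted descending,
    ``H = max_i min(J_(i), i / B)``.
    """
    j = np.sort(np.asarray(list(jaccards), dtype=float))[::-1]
    if j.size == 0:
        raise ValueError("empty Jaccard profile")
    if np.any((j < 0) | (j > 1)):
        raise ValueError("Jaccard values must lie in [0, 1]")
    frac = np.arange(1, j.size + 1) / j.size
    return float(np.max(np.minimum(j, frac)))


def _fit_and_cluster(pct_frame: pd.DataFrame, platforms, cfg: BuildConfig,
                     algorithm: str, k_values, seed: int):
    """Run variance filter -> PCA -> clustering on samples x genes percentiles."""
    est = AtlasPCA(threshold=cfg.threshold, n_components=cfg.n_components)
    est.fit(pct_frame, platform=platforms)
    coords = pd.DataFrame(est.training_coords_, index=pct_frame.index)
    results = {
        k: cluster(coords, algorithm=algorithm, k=k, seed=seed) for k in k_values
    }
    return est, results


def resample_stability(
    percentiles: ExpressionMatrix,
    annot: SampleAnnotation,
    cfg: BuildConfig | None = None,
    algorithm: str = "kmeans",
    k_values=(2, 3, 4, 5, 6, 7, 8, 9, 10),
    scheme: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
    unit: str = "sample",
) -> dict[int, StabilityReport]:
    """Stability of atlas clusters under jackknife or bootstrap resampling.

    For every resample the full pipeline is re-run from the raw percentile
    matrix; each original cluster is matched to the resample clustering by
    maximum Jaccard over the samples present in both.  Returns one
    :class:`StabilityReport` per k.
    """
    cfg = cfg or BuildConfig()
    k_values = sorted(k_values)
    rng = np.random.default_rng(seed)
    sample_ids = percentiles.sample_ids
    platforms = annot.platform_of(sample_ids)
    datasets = annot.dataset_of(sample_ids)

    pct = percentiles.to_samples_by_genes()
    full_est, full_clusterings = _fit_and_cluster(
        pct, platforms.to_numpy(), cfg, algorithm, k_values, seed
    )
    full_genes = set(full_est.selected_genes_)

    if scheme == "jackknife":
        unique_ds = pd.unique(datasets)
        if len(unique_ds) < 3:
            raise ValueError("jackknife requires at least 3 datasets")
        draws = [np.asarray(sample_ids)[datasets.to_numpy() != ds] for ds in unique_ds]
    elif scheme == "bootstrap":
        if n_boot < 1:
            raise ValueError("bootstrap requires n_boot >= 1")
        draws = []
        if unit == "sample":
            ids = np.asarray(sample_ids)
            for _ in range(n_boot):
                draws.append(pd.unique(rng.choice(ids, size=len(ids), replace=True)))
        elif unit == "dataset":
            unique_ds = pd.unique(datasets)
            ds_arr = datasets.to_numpy()
            ids = np.asarray(sample_ids)
            for _ in range(n_boot):
                picked = pd.unique(rng.choice(unique_ds, size=len(unique_ds), replace=True))
                draws.append(ids[np.isin(ds_arr, picked)])
        else:
            raise ValueError("unit must be 'sample' or 'dataset'")
    else:
        raise ValueError("scheme must be 'jackknife' or 'bootstrap'")

    per_k_jaccards: dict[int, dict] = {
        k: {lab: [] for lab in pd.unique(full_clusterings[k].labels)} for k in k_values
    }
    gene_overlap: list[float] = []
    n_used, n_skipped = 0, 0
    for ids in draws:
        ids = list(ids)
        sub_plat = platforms.loc[ids]
        if sub_plat.nunique() < 2 or len(ids) < max(k_values) or len(ids) < cfg.n_components:
            n_skipped += 1
            continue
        sub_pct = pct.loc[ids]
        try:
            est, clusterings = _fit_and_cluster(
                sub_pct, sub_plat.to_numpy(), cfg, algorithm, k_values, seed
            )
        except ValueError:
            n_skipped += 1
            continue
        n_used += 1
        gene_overlap.append(
            100.0 * len(full_genes & set(est.selected_genes_)) / len(full_genes)
        )
        shared = set(ids)
        for k in k_values:
            resample_sets = [
                clusterings[k].members(lab) for lab in pd.unique(clusterings[k].labels)
            ]
            for lab in per_k_jaccards[k]:
                orig = full_clusterings[k].members(lab) & shared
                best = max((jaccard(orig, rs) for rs in resample_sets), default=0.0)
                per_k_jaccards[k][lab].append(best)

    if n_skipped:
        warnings.warn(
            f"{n_skipped} resample(s) skipped (single platform, too few samples, "
            "or gene selection too small)",
            UserWarning,
            stacklevel=2,
        )
    if n_used == 0:
        raise ValueError("all resamples were skipped; stability undefined")

    reports = {}
    for k in k_values:
        reports[k] = StabilityReport(
            algorithm=algorithm,
            k=k,
            scheme=scheme,
            per_cluster_h={lab: h_index(js) for lab, js in per_k_jaccards[k].items()},
            n_resamples=n_used,
            n_skipped=n_skipped,
            gene_overlap_pct=gene_overlap,
        )
    return reports


def select_k(reports: dict[int, StabilityReport], k_values=None) -> int:
    """Pick k where the median H-index first starts to decrease.

    Returns the k immediately before the first strict decrease of the
    median H across the ascending k grid; if the median never decreases the
    largest k is returned with a warning.
    """
    if not reports:
        raise ValueError("no stability reports supplied")
    ks = sorted(k_values if k_values is not None else reports.keys())
    medians = [reports[k].median_h for k in ks]
    for i in range(1, len(medians)):
        if medians[i] < medians[i - 1]:
            return ks[i - 1]
    warnings.warn(
        "median H-index never decreased across the k grid; returning the largest k",
        UserWarning,
        stacklevel=2,
    )
    return ks[-1]
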