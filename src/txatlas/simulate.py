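"""Synthetic multi-platform expression data with known ground truth.

The generator emulates the structure of a curated multi-study compendium:
several cell types measured across microarray-like platforms (continuous
intensities with a positive background floor, never exactly zero) and
RNA-seq-like platforms (negative-binomial counts with exact zeros and
dropout), with gene-wise platform distortions, cell-type marker structure
and small per-dataset batch offsets.

The generative model, on a log2 abundance scale:

* baseline per gene ~ Normal(6, 2);
* each cell type owns a disjoint block of marker genes, shifted up by
  ``effect_size_log2`` in samples of that type;
* a random subset of genes (``frac_platform_affected_genes``) receives a
  platform-specific additive shift ~ Normal(0, distortion_strength) and a
  mild multiplicative slope on the centred signal — gene-level distortions
  that survive the per-sample rank transform, unlike a global shift;
* every dataset adds a small per-gene offset (residual batch);
* sample-level Gaussian noise with ``noise_sd``.

Microarray platforms emit ``2**log2signal`` plus a gamma-distributed
background; RNA-seq platforms emit negative-binomial counts with
Bernoulli dropout.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleAnnotation

__all__ = ["PlatformSpec", "SimConfig", "SimTruth", "simulate", "heldout_split"]


@dataclass
class PlatformSpec:
    name: str
    kind: str  # "microarray" | "rnaseq"
    distortion_strength: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("microarray", "rnaseq"):
            raise ValueError("platform kind must be 'microarray' or 'rnaseq'")
        if self.distortion_strength < 0:
            raise ValueError("distortion_strength must be >= 0")


def _default_platforms() -> list[PlatformSpec]:
    return [
        PlatformSpec("MA_A", "microarray"),
        PlatformSpec("MA_B", "microarray"),
        PlatformSpec("RNAseq_A", "rnaseq"),
        PlatformSpec("RNAseq_B", "rnaseq"),
    ]


@dataclass
class SimConfig:
    """Study conditions of the synthetic compendium.

    Defaults describe 10 cell types measured on 4 platforms (2
    microarray-like, 2 RNA-seq-like), 2 datasets per platform and 5
    samples per dataset per cell type — 400 samples over 2,000 genes, with
    half the genes platform-affected.
    """

    n_genes: int = 2000
    n_celltypes: int = 10
    platforms: list[PlatformSpec] = field(default_factory=_default_platforms)
    n_datasets_per_platform: int = 2
    samples_per_dataset_per_celltype: int = 5
    frac_platform_affected_genes: float = 0.5
    frac_marker_genes_per_celltype: float = 0.03
    effect_size_log2: float = 3.0
    noise_sd: float = 0.5
    dataset_offset_sd: float = 0.2
    dropout_rate: float = 0.05
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, name in [
            (self.frac_platform_affected_genes, "frac_platform_affected_genes"),
            (self.frac_marker_genes_per_celltype, "frac_marker_genes_per_celltype"),
            (self.dropout_rate, "dropout_rate"),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 2 or self.n_celltypes < 1:
            raise ValueError("need at least 2 genes and 1 cell type")
        if self.frac_marker_genes_per_celltype * self.n_celltypes > 1:
            raise ValueError("marker fractions exceed the gene pool")
        if not self.platforms:
            raise ValueError("at least one platform required")


@dataclass
class SimTruth:
    """Ground-truth labels for recovery tests."""

    gene_class: pd.Series       # per gene: marker:<ct> / platform_affected / both:<ct> / neutral
    marker_celltype: pd.Series  # per gene: owning cell type or NA
    platform_affected: pd.Series  # per gene: bool
    sample_celltype: pd.Series
    sample_platform: pd.Series
    sample_dataset: pd.Series


def simulate(cfg: SimConfig | None = None) -> tuple[ExpressionMatrix, SampleAnnotation, SimTruth]:
    """Draw one synthetic compendium; returns (expression, annotation, truth)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(g)]
    celltypes = [f"celltype{t + 1:02d}" for t in range(cfg.n_celltypes)]

    base = rng.normal(6.0, 2.0, size=g)

    # disjoint marker blocks per cell type
    n_marker = int(round(cfg.frac_marker_genes_per_celltype * g))
    shuffled = rng.permutation(g)
    marker_ct = np.full(g, -1)
    for t in range(cfg.n_celltypes):
        marker_ct[shuffled[t * n_marker:(t + 1) * n_marker]] = t

    affected = rng.random(g) < cfg.frac_platform_affected_genes

    # per (gene, platform) additive shift and multiplicative slope on the
    # centred log signal; only affected genes are distorted
    n_plat = len(cfg.platforms)
    shift = np.zeros((g, n_plat))
    slope = np.ones((g, n_plat))
    for p, spec in enumerate(cfg.platforms):
        shift[affected, p] = rng.normal(0.0, spec.distortion_strength, size=affected.sum())
        slope[affected, p] = np.clip(
            rng.normal(1.0, 0.1 * spec.distortion_strength, size=affected.sum()), 0.2, None
        )

    columns, sample_rows = {}, []
    for p, spec in enumerate(cfg.platforms):
        for d in range(cfg.n_datasets_per_platform):
            ds_name = f"{spec.name}_ds{d + 1}"
            ds_offset = rng.normal(0.0, cfg.dataset_offset_sd, size=g)
            for t, ct in enumerate(celltypes):
                for r in range(cfg.samples_per_dataset_per_celltype):
                    sid = f"{ds_name}_{ct}_s{r + 1}"
                    mu = base.copy()
                    mu[marker_ct == t] += cfg.effect_size_log2
                    mu = (mu - 6.0) * slope[:, p] + 6.0 + shift[:, p] + ds_offset
                    mu += rng.normal(0.0, cfg.noise_sd, size=g)
                    if spec.kind == "microarray":
                        vals = 2.0 ** mu + rng.gamma(shape=2.0, scale=15.0, size=g)
                    else:
                        mean = 2.0 ** np.clip(mu, None, 25.0)
                        size = cfg.nb_dispersion
                        vals = rng.negative_binomial(size, size / (size + mean)).astype(float)
                        vals[rng.random(g) < cfg.dropout_rate] = 0.0
                    columns[sid] = vals
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "dataset_id": ds_name,
                            "platform": spec.name,
                            "cell_type": ct,
                        }
                    )

    expr = ExpressionMatrix(pd.DataFrame(columns, index=gene_ids), "raw")
    annot = SampleAnnotation(pd.DataFrame(sample_rows))

    gidx = pd.Index(gene_ids, name="gene_id")
    marker_series = pd.Series(
        [celltypes[t] if t >= 0 else None for t in marker_ct], index=gidx
    )
    classes = []
    for i in range(g):
        if marker_ct[i] >= 0 and affected[i]:
            classes.append(f"both:{celltypes[marker_ct[i]]}")
        elif marker_ct[i] >= 0:
            classes.append(f"marker:{celltypes[marker_ct[i]]}")
        elif affected[i]:
            classes.append("platform_affected")
        else:
            classes.append("neutral")
    sidx = pd.Index([r["sample_id"] for r in sample_rows], name="sample_id")
    truth = SimTruth(
        gene_class=pd.Series(classes, index=gidx),
        marker_celltype=marker_series,
        platform_affected=pd.Series(affected, index=gidx),
        sample_celltype=pd.Series([r["cell_type"] for r in sample_rows], index=sidx),
        sample_platform=pd.Series([r["platform"] for r in sample_rows], index=sidx),
        sample_dataset=pd.Series([r["dataset_id"] for r in sample_rows], index=sidx),
    )
    return expr, annot, truth


def heldout_split(
    expr: ExpressionMatrix,
    annot: SampleAnnotation,
    truth: SimTruth,
    unit: str = "platform",
    held: str | None = None,
) -> tuple[tuple, tuple]:
    """Partition a simulated compendium by platform or dataset.

    Returns ``((train_expr, train_annot), (test_expr, test_annot))``; the
    training side must retain at least 2 platforms so the variance filter
    stays identifiable.
    """
    if unit not in ("platform", "dataset"):
        raise ValueError("unit must be 'platform' or 'dataset'")
    labels = truth.sample_platform if unit == "platform" else truth.sample_dataset
    if held not in set(labels):
        raise ValueError(f"{unit} {held!r} not present in the data")
    test_ids = labels.index[labels == held].tolist()
    train_ids = labels.index[labels != held].tolist()
    train_annot = annot.subset(train_ids)
    if train_annot.df["platform"].nunique() < 2:
        raise ValueError("holding out this unit leaves fewer than 2 training platforms")
    return (
        (expr.subset_samples(train_ids), train_annot),
        (expr.subset_samples(test_ids), annot.subset(test_ids)),
    )
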