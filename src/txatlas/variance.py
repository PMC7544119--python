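"""Per-gene variance partitioning.

Two per-gene decompositions are provided:

* a fixed-effect one-way ANOVA of expression on profiling platform, whose
  variance fraction ``sigma2_platform / (sigma2_platform + sigma2_resid)``
  equals the R-squared of the platform regression — the statistic the gene
  filter thresholds on; and
* a diagnostic two-random-intercept linear mixed model (LMM) on
  probit-transformed percentiles, partitioning variance into a biological
  class component (cell type, progenitor type or sample source), a platform
  component and a residual, with genes orderable by the class/platform
  variance ratio.

Population (divide-by-n) variances are used throughout the ANOVA so the
fraction is exactly R-squared and independent of variance convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import ExpressionMatrix, SampleAnnotation

__all__ = [
    "platform_variance_fraction",
    "platform_variance_fraction_frame",
    "lmm_class_platform",
    "variance_fraction_histogram",
]


def _group_codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes, len(uniques)


def platform_variance_fraction_frame(values: pd.DataFrame, platforms) -> pd.DataFrame:
    """Vectorised one-way platform ANOVA over a genes x samples frame.

    Returns a frame indexed by gene id with columns ``sigma2_platform``,
    ``sigma2_resid`` and ``fraction_platform``.
    """
    codes, n_plat = _group_codes(platforms)
    if n_plat < 2:
        raise ValueError("platform effect unidentifiable: need at least 2 platforms")
    if len(codes) != values.shape[1]:
        raise ValueError("platform labels do not match sample count")
    counts = np.bincount(codes, minlength=n_plat)
    if (counts < 2).any():
        few = counts[counts < 2]
        warnings.warn(
            f"{len(few)} platform(s) have a single sample; their fitted mean absorbs "
            "the sample exactly and inflates the platform fraction",
            UserWarning,
            stacklevel=2,
        )
    arr = values.to_numpy(dtype=float)
    n = arr.shape[1]
    # per-gene group means -> fitted values
    sums = np.zeros((arr.shape[0], n_plat))
    np.add.at(sums.T, codes, arr.T)
    group_means = sums / counts
    fitted = group_means[:, codes]
    grand = arr.mean(axis=1, keepdims=True)
    s2_platform = ((fitted - grand) ** 2).mean(axis=1)
    s2_resid = ((arr - fitted) ** 2).mean(axis=1)
    total = s2_platform + s2_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(total > 0, s2_platform / total, 0.0)
    return pd.DataFrame(
        {
            "sigma2_platform": s2_platform,
            "sigma2_resid": s2_resid,
            "fraction_platform": fraction,
        },
        index=values.index.rename("gene_id"),
    )


def platform_variance_fraction(
    percentiles: ExpressionMatrix, annot: SampleAnnotation
) -> pd.DataFrame:
    """Per-gene fraction of variance attributable to platform.

    Fits, for each gene, the fixed-effect model ``y = X_p beta_p + eps``
    where ``X_p`` encodes platform membership, and reports
    ``var(X_p beta_p) / (var(X_p beta_p) + var(eps))``.
    """
    missing = set(percentiles.sample_ids) - set(annot.df.index)
    if missing:
        raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
    platforms = annot.platform_of(percentiles.sample_ids)
    return platform_variance_fraction_frame(percentiles.values, platforms)


def probit_percentiles(pct: np.ndarray, n_genes: int) -> np.ndarray:
    """Probit transform with a continuity correction keeping values finite.

    Percentiles are first squeezed into (0, 1) as
    ``p' = (p * (G - 1) + 0.5) / G`` for a G-gene universe, then mapped
    through the standard normal quantile function.
    """
    squeezed = (pct * (n_genes - 1) + 0.5) / n_genes
    return norm.ppf(squeezed)


def lmm_class_platform(
    percentiles: ExpressionMatrix,
    annot: SampleAnnotation,
    class_field: str = "cell_type",
    probit: bool = True,
) -> pd.DataFrame:
    """Class vs platform variance components per gene under a crossed LMM.

    For each gene the model ``y = mu + a_class + a_platform + eps`` is
    fitted by REML, with ``a_class ~ N(0, I sigma2_class)`` and
    ``a_platform ~ N(0, I sigma2_platform)`` crossed random intercepts.
    Percentiles are probit-transformed first to meet the LMM normality
    assumption (set ``probit=False`` if the input is already
    normal-scale).

    Returns a frame with the three variance components, the
    class/platform ratio (``inf`` when the platform component is zero and
    the class component positive) and a ``converged`` flag; genes whose
    fit fails are flagged rather than dropped.
    """
    import statsmodels.formula.api as smf

    cls = annot.class_of(percentiles.sample_ids, class_field)
    if cls.isna().any():
        raise ValueError(f"{class_field} must be non-null for all samples")
    plat = annot.platform_of(percentiles.sample_ids)
    if cls.nunique() < 2 or plat.nunique() < 2:
        raise ValueError("need at least 2 levels in both class and platform")

    arr = percentiles.values.to_numpy(dtype=float)
    if probit:
        arr = probit_percentiles(arr, percentiles.n_genes)

    base = pd.DataFrame(
        {"cls": cls.to_numpy().astype(str), "plat": plat.to_numpy().astype(str), "grp": 1}
    )
    records = []
    for i, gene in enumerate(percentiles.gene_ids):
        y = arr[i]
        rec = {
            "gene_id": gene,
            "sigma2_class": np.nan,
            "sigma2_platform_r": np.nan,
            "sigma2_resid_r": np.nan,
            "class_platform_ratio": np.nan,
            "converged": False,
        }
        if np.ptp(y) > 0:
            df = base.assign(y=y)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(
                        "y ~ 1",
                        df,
                        groups="grp",
                        re_formula="0",
                        vc_formula={"cls": "0 + C(cls)", "plat": "0 + C(plat)"},
                    )
                    res = model.fit(reml=True, method="lbfgs")
                    if not res.converged:
                        # boundary estimates (a component at 0) often trip
                        # gradient methods; Powell is slower but robust there
                        res = model.fit(reml=True, method="powell")
                if res.converged:
                    s2c = float(res.vcomp[0])
                    s2p = float(res.vcomp[1])
                    s2e = float(res.scale)
                    if s2p > 0:
                        ratio = s2c / s2p
                    else:
                        ratio = np.inf if s2c > 0 else np.nan
                    rec.update(
                        sigma2_class=s2c,
                        sigma2_platform_r=s2p,
                        sigma2_resid_r=s2e,
                        class_platform_ratio=ratio,
                        converged=True,
                    )
            except (np.linalg.LinAlgError, ValueError):
                pass
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("gene_id")


def variance_fraction_histogram(genevar: pd.DataFrame, bins: int = 20) -> np.ndarray:
    """Histogram counts of the platform variance fraction over [0, 1]."""
    if len(genevar) == 0:
        raise ValueError("empty gene variance table")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, _ = np.histogram(
        genevar["fraction_platform"].to_numpy(), bins=bins, range=(0.0, 1.0)
    )
    return counts
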