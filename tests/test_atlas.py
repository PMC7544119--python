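"""Atlas construction: gene selection, PCA identity, recursion, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import txatlas as tx


def _genevar(fracs: dict) -> pd.DataFrame:
    return pd.DataFrame({"fraction_platform": pd.Series(fracs)})


class TestSelectGenes:
    def test_strict_threshold_boundary_excluded(self):
        table = _genevar({"g1": 0.1, "g2": 0.3, "g3": 0.19, "g4": 0.20})
        assert tx.select_genes(table, 0.2) == ["g1", "g3"]

    def test_threshold_one_keeps_everything(self):
        table = _genevar({"g1": 0.5, "g2": 0.99})
        assert tx.select_genes(table, 1.0) == ["g1", "g2"]

    def test_selection_nested_in_threshold(self):
        rng = np.random.default_rng(3)
        table = _genevar({f"g{i}": f for i, f in enumerate(rng.random(100))})
        assert set(tx.select_genes(table, 0.1)) <= set(tx.select_genes(table, 0.5))

    def test_empty_selection_advises(self):
        with pytest.raises(ValueError, match="larger threshold"):
            tx.select_genes(_genevar({"g1": 0.9}), 0.2)


class TestCommonGeneUniverse:
    def _mat(self, genes):
        df = pd.DataFrame(np.ones((len(genes), 2)), index=genes, columns=["x", "y"])
        df.columns = [f"{genes[0]}_{c}" for c in df.columns]
        return tx.ExpressionMatrix(df)

    def test_intersection(self):
        mats = [self._mat(["a", "b", "c"]), self._mat(["b", "c", "d"])]
        assert tx.common_gene_universe(mats, {0: "P1", 1: "P2"}) == ["b", "c"]

    def test_identical_sets(self):
        mats = [self._mat(["a", "b"]), self._mat(["b", "a"])]
        assert tx.common_gene_universe(mats, {0: "P1", 1: "P2"}) == ["a", "b"]

    def test_union_within_platform(self):
        mats = [self._mat(["a"]), self._mat(["b"]), self._mat(["a", "b"])]
        assert tx.common_gene_universe(mats, {0: "P1", 1: "P1", 2: "P2"}) == ["a", "b"]

    def test_disjoint_errors(self):
        mats = [self._mat(["a"]), self._mat(["b"])]
        with pytest.raises(ValueError, match="all platforms"):
            tx.common_gene_universe(mats, {0: "P1", 1: "P2"})


def test_training_coords_reproduced_by_transform(small_atlas, small_pct):
    """PCA identity: pushing the training percentiles through the stored
    means and loadings reproduces the stored coordinates."""
    coords = small_atlas.transform_percentiles(small_pct.to_samples_by_genes())
    np.testing.assert_allclose(
        coords, small_atlas.training_coords.to_numpy(), atol=1e-10
    )


def test_fit_is_deterministic(small_sim, small_pct):
    _, annot, _ = small_sim
    a = tx.fit_atlas(small_pct, annot, tx.BuildConfig(seed=1))
    b = tx.fit_atlas(small_pct, annot, tx.BuildConfig(seed=1))
    assert a.selected_genes == b.selected_genes
    np.testing.assert_array_equal(
        a.training_coords.to_numpy(), b.training_coords.to_numpy()
    )


def test_platform_affected_genes_depleted(small_sim, small_atlas):
    """Genes with injected platform effects survive the 0.2 filter at least
    5-fold less often than unaffected genes."""
    _, _, truth = small_sim
    sel = set(small_atlas.selected_genes)
    aff = truth.platform_affected
    rate_affected = np.mean([g in sel for g in aff.index[aff]])
    rate_clean = np.mean([g in sel for g in aff.index[~aff]])
    assert rate_clean >= 5 * rate_affected


def test_null_simulation_keeps_most_genes():
    plats = [
        tx.PlatformSpec("MA_A", "microarray", 0.0),
        tx.PlatformSpec("MA_B", "microarray", 0.0),
        tx.PlatformSpec("RS_A", "rnaseq", 0.0),
        tx.PlatformSpec("RS_B", "rnaseq", 0.0),
    ]
    expr, annot, _ = tx.simulate(
        tx.SimConfig(n_genes=800, n_celltypes=5, platforms=plats, seed=31)
    )
    model = tx.fit_atlas(tx.rank_percentile(expr), annot, tx.BuildConfig(threshold=0.2))
    assert len(model.selected_genes) >= 0.95 * 800


def test_gene_count_monotone_in_threshold(small_sim, small_pct):
    _, annot, _ = small_sim
    counts = [
        len(tx.fit_atlas(small_pct, annot, tx.BuildConfig(threshold=t)).selected_genes)
        for t in (0.1, 0.3, 0.6, 1.0)
    ]
    assert counts == sorted(counts)


def test_platform_mixing_decreases_with_threshold(small_sim, small_pct):
    """K-means at k = number of platforms aligns less with platform labels
    as the filter tightens."""
    from sklearn.metrics import adjusted_rand_score

    _, annot, truth = small_sim
    aris = []
    for t in (0.8, 0.6, 0.4, 0.2):
        m = tx.fit_atlas(small_pct, annot, tx.BuildConfig(threshold=t))
        cl = tx.cluster(m.training_coords, "kmeans", k=4, seed=0)
        aris.append(
            adjusted_rand_score(truth.sample_platform.loc[cl.labels.index], cl.labels)
        )
    assert all(a >= b - 1e-12 for a, b in zip(aris, aris[1:]))
    assert aris[-1] < aris[0]


def test_subatlas_identity_subset(small_sim, small_pct, small_atlas):
    _, annot, _ = small_sim
    again = tx.build_subatlas(small_pct, annot, small_pct.sample_ids, tx.BuildConfig())
    assert again.selected_genes == small_atlas.selected_genes
    np.testing.assert_allclose(
        again.training_coords.to_numpy(),
        small_atlas.training_coords.to_numpy(),
        atol=1e-10,
    )


def test_subatlas_single_platform_errors(small_sim, small_pct):
    _, annot, truth = small_sim
    one_plat = truth.sample_platform.index[truth.sample_platform == "MA_A"].tolist()
    with pytest.raises(ValueError, match="single platform"):
        tx.build_subatlas(small_pct, annot, one_plat, tx.BuildConfig())
    with pytest.raises(ValueError, match="empty"):
        tx.build_subatlas(small_pct, annot, [], tx.BuildConfig())


def test_subatlas_resolves_subtypes_better():
    """Rebuilding on a pair of cell types separates them more cleanly (in
    the 3D display space) than the parent's crowded coordinates do: with 10
    types sharing 3 display components, any single pair is poorly resolved
    until the recursion dedicates the components to it."""
    expr, annot, truth = tx.simulate(tx.SimConfig(seed=13))
    pct = tx.rank_percentile(expr)
    parent = tx.fit_atlas(pct, annot, tx.BuildConfig())
    ct = truth.sample_celltype
    sub_ids = ct.index[ct.isin(["celltype01", "celltype02"])].tolist()
    child = tx.build_subatlas(pct, annot, sub_ids, tx.BuildConfig())
    labels = ct.loc[sub_ids]
    sil_parent = silhouette_score(parent.training_coords.loc[sub_ids].iloc[:, :3], labels)
    sil_child = silhouette_score(child.training_coords.loc[sub_ids].iloc[:, :3], labels)
    assert sil_child > sil_parent


class TestComponentDiagnostics:
    def test_all_tied_scores_give_zero(self, two_platform_annot):
        model = _toy_model(coords=np.zeros((6, 3)), samples=two_platform_annot.sample_ids)
        diag = tx.component_platform_dependence(model, two_platform_annot, n_components=3)
        assert (diag["kw_h_statistic"] == 0).all()

    def test_full_separation_closed_form(self, two_platform_annot):
        # ranks 1-3 vs 4-6: H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7
        coords = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        model = _toy_model(coords=coords, samples=two_platform_annot.sample_ids)
        diag = tx.component_platform_dependence(model, two_platform_annot, n_components=1)
        assert diag["kw_h_statistic"].iloc[0] == pytest.approx(27 / 7, abs=1e-10)

    def test_small_platform_dropped_with_warning(self):
        annot = tx.SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": ["a1", "a2", "b1", "b2", "c1"],
                    "dataset_id": ["d"] * 5,
                    "platform": ["P1", "P1", "P2", "P2", "P3"],
                }
            )
        )
        coords = np.arange(5, dtype=float)[:, None]
        model = _toy_model(coords=coords, samples=annot.sample_ids)
        with pytest.warns(UserWarning, match="P3"):
            diag = tx.component_platform_dependence(model, annot, n_components=1)
        assert diag["n_platforms"].iloc[0] == 2


def _toy_model(coords: np.ndarray, samples) -> tx.AtlasModel:
    k = coords.shape[1]
    genes = [f"g{i}" for i in range(k + 1)]
    loadings = np.eye(k, k + 1)
    return tx.AtlasModel(
        selected_genes=genes,
        gene_means=pd.Series(0.5, index=genes),
        loadings=loadings,
        explained_variance=np.linspace(1.0, 0.5, k),
        training_coords=pd.DataFrame(
            coords, index=samples, columns=[f"PC{i+1}" for i in range(k)]
        ),
        threshold=0.2,
        n_components=k,
    )


def test_build_config_validation():
    with pytest.raises(ValueError):
        tx.BuildConfig(threshold=1.5)
    with pytest.raises(ValueError):
        tx.BuildConfig(threshold=0.0)
    with pytest.raises(ValueError):
        tx.BuildConfig(n_components=0)


def test_fit_atlas_requires_enough_samples(small_sim, small_pct):
    _, annot, _ = small_sim
    few = small_pct.subset_samples(small_pct.sample_ids[:4])
    with pytest.raises(ValueError, match="components"):
        tx.fit_atlas(few, annot, tx.BuildConfig(n_components=10))
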