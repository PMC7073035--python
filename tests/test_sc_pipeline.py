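import hashlib

import numpy as np
import pandas as pd
import pytest

from dsbscore.genesets import GeneSet
from dsbscore.sc import (QC_PRESETS, QCThresholds, annotate_clusters_overlap,
                         cluster_graph, compute_qc_metrics, embed_pca,
                         filter_cells, knn_graph, normalize_log,
                         rank_markers_ttest, select_common_hvg)

from conftest import make_adata


# ---------------------------------------------------------------- QC metrics

def test_qc_metrics_match_dense_oracle(rng):
    counts = rng.integers(0, 20, size=(50, 30))
    genes = [f"MT-{j}" if j < 3 else f"G{j}" for j in range(30)]
    ad = compute_qc_metrics(make_adata(counts, genes=genes))
    dense = counts.astype(float)
    assert np.array_equal(ad.obs["total_counts"], dense.sum(1))
    assert np.array_equal(ad.obs["n_genes"], (dense > 0).sum(1))
    expect = np.divide(dense[:, :3].sum(1), dense.sum(1),
                       out=np.zeros(50), where=dense.sum(1) > 0)
    assert np.allclose(ad.obs["mito_frac"], expect)


def test_mito_fraction_edge_cases():
    ad = compute_qc_metrics(make_adata([[5, 0], [0, 0]], genes=["MT-ND1", "G1"]))
    assert ad.obs["mito_frac"].tolist() == [1.0, 0.0]
    assert ad.obs["zero_count_cell"].tolist() == [False, True]
    ad2 = compute_qc_metrics(make_adata([[1, 2]], genes=["A", "B"]))
    assert ad2.obs["mito_frac"].tolist() == [0.0]


# ------------------------------------------------------------- cell filtering

def test_e15_boundary_is_strictly_more_than():
    # one gene per count so gene window passes; cell at exactly 2000 UMIs drops
    counts = np.zeros((2, 3000), dtype=int)
    counts[0, :2000] = 1
    counts[1, :2001] = 1
    ad = compute_qc_metrics(make_adata(counts))
    kept = filter_cells(ad, QC_PRESETS["e15_mouse"])
    assert list(kept.obs_names) == ["c0001"]


def test_organoid_mito_boundary_is_strictly_fewer_than():
    counts = np.zeros((2, 1000), dtype=int)
    counts[0, :998] = 1
    counts[0, 998] = 2  # 2/1000 mito fraction = 0.002 -> removed
    counts[1, :997] = 1  # 0 mito, 997 genes
    genes = [f"G{j}" for j in range(998)] + ["MT-ND1", "MT-CO1"]
    ad = compute_qc_metrics(make_adata(counts, genes=genes))
    kept = filter_cells(ad, QC_PRESETS["organoid"])
    assert list(kept.obs_names) == ["c0001"]


def test_filter_matches_brute_force_oracle_and_is_idempotent(rng):
    counts = rng.integers(0, 40, size=(100, 200))
    genes = [f"MT-{j}" if j < 5 else f"G{j}" for j in range(200)]
    ad = compute_qc_metrics(make_adata(counts, genes=genes))
    t = QCThresholds(min_umi=3500, min_genes=150, max_genes=190,
                     max_umi=4200, max_mito_fraction=0.03)
    kept = filter_cells(ad, t)
    expected = []
    for i in range(100):
        row = counts[i].astype(float)
        umi, ng = row.sum(), (row > 0).sum()
        mito = row[:5].sum() / umi if umi else 0.0
        if umi > 3500 and 150 <= ng <= 190 and umi < 4200 and mito < 0.03:
            expected.append(f"c{i:04d}")
    assert list(kept.obs_names) == expected
    again = filter_cells(compute_qc_metrics(kept), t)
    assert list(again.obs_names) == expected


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        QCThresholds(min_genes=10, max_genes=5)


# ------------------------------------------------------------ normalization

def test_normalize_log_small_example():
    ad = normalize_log(make_adata([[2, 2, 0]]), target_sum=100)
    layer = ad.layers["lognorm"].toarray()[0]
    assert np.allclose(layer, [np.log(51), np.log(51), 0.0])


def test_normalize_preserves_raw_and_scales_to_target(rng):
    counts = rng.integers(0, 15, size=(40, 25))
    counts[3] = 0  # zero cell stays zero
    ad = make_adata(counts)
    digest = hashlib.sha256(ad.X.toarray().tobytes()).hexdigest()
    normalize_log(ad, target_sum=1e4)
    assert hashlib.sha256(ad.X.toarray().tobytes()).hexdigest() == digest
    pre_log = np.expm1(ad.layers["lognorm"].toarray())
    sums = pre_log.sum(1)
    nonzero = counts.sum(1) > 0
    assert np.allclose(sums[nonzero], 1e4)
    assert np.all(pre_log[~nonzero] == 0)


# ---------------------------------------------------------------------- HVG

def test_hvg_finds_planted_high_dispersion_genes(rng):
    n = 300
    counts = rng.poisson(5.0, size=(n, 30))
    # three genes with planted bimodal (high-dispersion) expression
    for j in (4, 11, 23):
        counts[:, j] = rng.poisson(np.where(rng.random(n) < 0.5, 0.5, 30.0))
    ad = normalize_log(make_adata(counts))
    top = select_common_hvg(ad, n_genes=3)
    assert set(top) == {"G4", "G11", "G23"}


def test_constant_gene_never_selected(rng):
    counts = rng.integers(1, 10, size=(100, 10))
    counts[:, 0] = 7
    ad = normalize_log(make_adata(counts))
    assert "G0" not in select_common_hvg(ad, n_genes=9)


def test_two_identical_batches_intersection_is_top_list(rng):
    counts = rng.negative_binomial(2, 0.2, size=(80, 40))
    stacked = np.vstack([counts, counts])
    ad = make_adata(stacked, batch=["a"] * 80 + ["b"] * 80)
    normalize_log(ad)
    both = select_common_hvg(ad, n_per_batch=10)
    single = select_common_hvg(ad[ad.obs["batch"] == "a"].copy(), n_per_batch=10)
    assert set(both) == set(single)
    assert len(both) == 10


# ---------------------------------------------------------------------- PCA

def test_pca_on_a_line_explains_everything(rng):
    t = rng.normal(size=60)
    x = np.column_stack([2 * t, -t, 3 * t]) * 10 + 100
    counts = np.maximum(x, 0).astype(int)
    ad = make_adata(counts)
    ad.layers["lognorm"] = np.column_stack([2 * t, -t, 3 * t])
    coords, evr = embed_pca(ad, n_pcs=2)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_matches_eigendecomposition_oracle(rng):
    x = rng.normal(size=(30, 8))
    ad = make_adata(np.zeros((30, 8), dtype=int))
    ad.layers["lognorm"] = x
    coords, evr = embed_pca(ad, n_pcs=4)
    xc = x - x.mean(0)
    evals, evecs = np.linalg.eigh(xc.T @ xc / (30 - 1))
    order = np.argsort(-evals)
    ref = xc @ evecs[:, order[:4]]
    for j in range(4):
        assert np.allclose(np.abs(coords[:, j]), np.abs(ref[:, j]), atol=1e-8)
    assert np.all(np.diff(evr) <= 1e-12)
    assert evr.sum() <= 1 + 1e-9


def test_pca_clips_excess_components(rng):
    ad = make_adata(rng.integers(0, 5, size=(6, 4)))
    normalize_log(ad)
    coords, evr = embed_pca(ad, n_pcs=50)
    assert coords.shape[1] <= 4


# -------------------------------------------------------------------- graph

def test_knn_symmetrizes_collinear_points():
    coords = np.array([[0.0], [1.0], [2.0]])
    adj = knn_graph(coords, k=1)
    a = adj.toarray()
    assert a[1, 0] > 0 and a[1, 2] > 0  # middle links to both after union
    assert np.allclose(a, a.T)
    assert a[0, 1] == pytest.approx(1 / 2)  # weight 1/(1+d)


def test_knn_matches_brute_force_neighbors(rng):
    coords = rng.normal(size=(120, 5))
    k = 7
    adj = knn_graph(coords, k=k)
    d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    for i in range(120):
        nn = set(np.argsort(d[i], kind="stable")[:k])
        got = set(adj[i].indices)
        assert nn <= got  # union symmetrization may only add edges


def test_graph_connected_on_gaussian_blob(rng):
    from scipy.sparse.csgraph import connected_components
    adj = knn_graph(rng.normal(size=(400, 10)), k=15)
    assert connected_components(adj, directed=False)[0] == 1


def test_cluster_two_blobs_and_determinism(rng):
    coords = np.vstack([rng.normal(0, 0.3, size=(100, 4)),
                        rng.normal(5, 0.3, size=(100, 4))])
    adj = knn_graph(coords, k=10)
    # a gentle resolution recovers the two planted communities exactly
    labels = cluster_graph(adj, resolution=0.05, seed=0)
    assert labels.shape == (200,)
    assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1
    assert labels[0] != labels[150]
    default = cluster_graph(adj, seed=0)
    assert np.array_equal(default, cluster_graph(adj, seed=0))  # seeded determinism
    # every cell gets exactly one id, and blobs never mix even at resolution 1
    assert set(default[:100]).isdisjoint(set(default[100:]))
    louv = cluster_graph(adj, resolution=0.05, seed=0, algorithm="louvain")
    assert len(set(louv[:100])) == 1 and louv[0] != louv[150]


# ------------------------------------------------------------------- markers

def test_planted_marker_ranks_first(rng):
    counts = rng.poisson(2.0, size=(60, 20))
    counts[:20, 5] += 50  # cluster A exclusively expresses G5 highly
    ad = normalize_log(make_adata(counts))
    ad.obs["cluster"] = ["A"] * 20 + ["B"] * 40
    markers = rank_markers_ttest(ad, "cluster", top_n=5)
    assert markers["A"].iloc[0]["gene"] == "G5"


def test_constant_gene_has_zero_t(rng):
    counts = rng.poisson(3.0, size=(30, 5))
    ad = make_adata(counts)
    layer = ad.X.toarray().astype(float)
    layer[:, 2] = 1.0
    ad.layers["lognorm"] = layer
    ad.obs["cluster"] = ["A"] * 15 + ["B"] * 15
    markers = rank_markers_ttest(ad, "cluster", top_n=5)
    for tab in markers.values():
        assert "G2" not in set(tab["gene"])


def test_welch_statistic_matches_formula_oracle():
    from scipy import stats as sps
    x = np.array([[1.0, 2, 0, 4, 1], [2, 1, 1, 5, 0], [0, 3, 0, 4, 2],
                  [5, 0, 2, 1, 1], [6, 1, 3, 0, 0], [4, 0, 2, 1, 3]])
    ad = make_adata(np.zeros((6, 5), dtype=int))
    ad.layers["lognorm"] = x
    ad.obs["cluster"] = ["A"] * 3 + ["B"] * 3
    markers = rank_markers_ttest(ad, "cluster", top_n=5)
    for _, row in markers["A"].iterrows():
        j = int(row["gene"][1:])
        t_ref, p_ref = sps.ttest_ind(x[:3, j], x[3:, j], equal_var=False)
        assert row["t"] == pytest.approx(t_ref)
        assert row["p"] == pytest.approx(p_ref)


def test_tiny_cluster_skipped(rng):
    ad = normalize_log(make_adata(rng.poisson(2.0, size=(10, 4))))
    ad.obs["cluster"] = ["A"] * 2 + ["B"] * 8
    assert "A" not in rank_markers_ttest(ad, "cluster")


# ---------------------------------------------------------------- annotation

def _ref(name, symbols):
    return GeneSet(name, "MARKER", "human", tuple((s, "none") for s in symbols))


def test_annotation_exact_match_and_unassigned():
    markers = {"0": pd.DataFrame({"gene": ["RHO", "GNAT1", "NRL"],
                                  "t": [5, 4, 3], "p": [0] * 3}),
               "1": pd.DataFrame({"gene": ["ZZZ1", "ZZZ2"],
                                  "t": [5, 4], "p": [0] * 2})}
    refs = [_ref("rod", ["RHO", "GNAT1", "NRL"]), _ref("cone", ["ARR3"])]
    ann = annotate_clusters_overlap(markers, refs)
    assert ann["0"]["label"] == "rod" and ann["0"]["score"] == 1.0
    assert ann["1"]["label"] == "unassigned" and ann["1"]["score"] == 0.0


def test_annotation_tie_breaks_by_intersection_then_label():
    markers = {"0": pd.DataFrame({"gene": ["A", "B"], "t": [2, 1], "p": [0, 0]})}
    refs = [_ref("beta", ["A", "B"]), _ref("alpha", ["A", "B"])]
    ann = annotate_clusters_overlap(markers, refs)
    assert ann["0"]["label"] == "alpha"  # equal score & intersection -> lexical
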