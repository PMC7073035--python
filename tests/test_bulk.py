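import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dsbscore.bulk import (BulkTable, build_pathway_table, dsb_pca_spearman,
                           log_tpm, pairwise_pathway_tests, quantile_normalize,
                           timecourse_summary)
from dsbscore.genesets import load_cell_cycle_sets, load_dsb_sets
from dsbscore.simulate import SimConfig, simulate_bulk_timecourse

DSB_GENES = [g for gs in load_dsb_sets("human") for g in gs.symbols]


def _table(values, samples=None, genes=None, species="human", days=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"species": species,
                         "replicate": range(1, len(samples) + 1)}, index=samples)
    if days is not None:
        meta["day"] = days
    return BulkTable(pd.DataFrame(values, index=genes, columns=samples), meta)


# ------------------------------------------------------------------ log_tpm

def test_log_tpm_values():
    t = log_tpm(_table([[0, 3], [1, 7]]))
    assert t.expr.iloc[0, 0] == 0.0
    assert t.expr.iloc[0, 1] == pytest.approx(2.0)  # log2(4)
    assert t.log_transformed


def test_log_tpm_elementwise_oracle(rng):
    x = rng.gamma(2.0, 10.0, size=(30, 6))
    t = log_tpm(_table(x))
    assert np.allclose(t.expr.to_numpy(), np.log2(x + 1))


def test_negative_values_rejected():
    with pytest.raises(ValueError):
        BulkTable(pd.DataFrame([[-1.0]], index=["g"], columns=["s"]),
                  pd.DataFrame({"species": ["human"]}, index=["s"]))


# --------------------------------------------------------- quantile normalize

def test_quantile_normalize_two_sample_example():
    t = quantile_normalize(_table(np.array([[2, 1], [4, 2], [6, 3]])))
    assert t.expr["s0"].tolist() == [1.5, 3.0, 4.5]
    assert t.expr["s1"].tolist() == [1.5, 3.0, 4.5]


def test_sorted_vectors_identical_within_group(rng):
    x = rng.gamma(2.0, 5.0, size=(40, 5))
    t = quantile_normalize(_table(x))
    cols = [np.sort(t.expr[c].to_numpy()) for c in t.expr]
    for c in cols[1:]:
        assert np.allclose(cols[0], c)


def test_quantile_normalize_idempotent_and_mean_preserving(rng):
    x = rng.gamma(2.0, 5.0, size=(25, 4))
    t1 = quantile_normalize(_table(x))
    t2 = quantile_normalize(t1)
    assert np.allclose(t1.expr.to_numpy(), t2.expr.to_numpy())
    assert t1.expr.to_numpy().mean() == pytest.approx(x.mean())


def test_tie_handling_matches_enumeration_oracle(rng):
    x = rng.integers(0, 5, size=(12, 3)).astype(float)  # many ties
    t = quantile_normalize(_table(x))
    ref = np.sort(x, axis=0).mean(axis=1)
    for j, col in enumerate(t.expr.columns):
        vals = x[:, j]
        order = np.argsort(vals, kind="stable")
        mapped = np.empty(12)
        mapped[order] = ref
        expect = np.array([mapped[vals == v].mean() for v in vals])
        assert np.allclose(t.expr[col].to_numpy(), expect)


def test_single_sample_group_passthrough(rng):
    x = rng.gamma(2.0, 5.0, size=(10, 3))
    tab = _table(x, species="human")
    tab.meta["species"] = ["human", "human", "mouse"]  # mouse group of one
    t = quantile_normalize(tab)
    assert np.allclose(t.expr["s2"].to_numpy(), x[:, 2])


def test_groups_normalized_independently(rng):
    x = rng.gamma(2.0, 5.0, size=(20, 4))
    tab = _table(x)
    tab.meta["species"] = ["a", "a", "b", "b"]
    t = quantile_normalize(tab)
    assert np.allclose(np.sort(t.expr["s0"]), np.sort(t.expr["s1"]))
    assert not np.allclose(np.sort(t.expr["s0"]), np.sort(t.expr["s2"]))


# ------------------------------------------------------------- pathway table

def test_pathway_table_full_panel_counts():
    t = _table(np.ones((17, 2)), genes=DSB_GENES)
    long = build_pathway_table(t)
    assert len(long) == 17 * 2
    per = long.groupby(["sample", "pathway"], observed=True).size().unstack()
    assert (per["NHEJ"] == 4).all() and (per["MMEJ"] == 5).all() and (per["HDR"] == 8).all()


def test_pathway_table_missing_gene_logged_not_fatal():
    genes = [g for g in DSB_GENES if g != "EXO1"]
    long = build_pathway_table(_table(np.ones((16, 3)), genes=genes, species="macaque"))
    hdr = long[long["pathway"] == "HDR"]
    assert hdr.groupby("sample").size().eq(7).all()


def test_pathway_table_empty_pathway_errors():
    genes = [g for g in DSB_GENES if g not in load_dsb_sets("human")[0].symbols]
    with pytest.raises(ValueError, match="NHEJ"):
        build_pathway_table(_table(np.ones((13, 2)), genes=genes))


# -------------------------------------------------------------- paired tests

def test_identical_pathway_vectors_p_one():
    t = _table(np.ones((17, 4)), genes=DSB_GENES)
    rep = pairwise_pathway_tests(build_pathway_table(t))
    assert (rep["p_value"] == 1.0).all()
    assert (rep["method"] == "exact").all()


def test_three_pairs_all_one_direction():
    x = np.ones((17, 3))
    nhej_rows = [DSB_GENES.index(g) for g in load_dsb_sets("human")[0].symbols]
    x[nhej_rows] = [[5, 6, 7]] * 4  # NHEJ higher in every replicate
    rep = pairwise_pathway_tests(build_pathway_table(_table(x, genes=DSB_GENES)))
    row = rep[(rep.pathway_a == "MMEJ") & (rep.pathway_b == "NHEJ")].iloc[0]
    assert row["p_value"] == pytest.approx(0.25)  # 2/2^3
    assert row["direction"] == -1


def test_single_replicate_errors():
    t = _table(np.ones((17, 1)), genes=DSB_GENES)
    with pytest.raises(ValueError):
        pairwise_pathway_tests(build_pathway_table(t))


# ----------------------------------------------------------------- timecourse

def test_timecourse_means_match_loop_oracle(rng):
    x = rng.gamma(2.0, 5.0, size=(17, 6))
    t = _table(x, genes=DSB_GENES, days=[0, 0, 4, 4, 8, 8])
    summ = timecourse_summary(t, load_dsb_sets("human"))
    nhej_genes = load_dsb_sets("human")[0].symbols
    rows_idx = [DSB_GENES.index(g) for g in nhej_genes]
    for day, cols in [(0, [0, 1]), (4, [2, 3]), (8, [4, 5])]:
        vals = x[np.ix_(rows_idx, cols)].ravel()
        row = summ[(summ["day"] == day) & (summ["set"] == "NHEJ")].iloc[0]
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["n_values"] == vals.size


def test_synthetic_timecourse_shapes():
    table, _ = simulate_bulk_timecourse(SimConfig(seed=3), cycle_off_day=4.0)
    lt = log_tpm(table)
    sets = load_dsb_sets("human") + [s for s in load_cell_cycle_sets("human")
                                     if s.name == "G2M"]
    summ = timecourse_summary(lt, sets)
    wide = summ.pivot(index="day", columns="set", values="mean")
    assert wide.loc[14.0, "G2M"] < 0.5 * wide.loc[0.0, "G2M"]
    assert wide.loc[14.0, "HDR"] < 0.5 * wide.loc[0.0, "HDR"]
    nhej = wide["NHEJ"]
    assert abs(nhej.iloc[-1] - nhej.iloc[0]) / nhej.iloc[0] < 0.1  # flat


# --------------------------------------------------------------- PCA/Spearman

def test_spearman_basics(rng):
    x = rng.gamma(2.0, 5.0, size=(17, 3))
    x[:, 2] = x[:, 0]  # duplicate sample
    coords, rho = dsb_pca_spearman([_table(x, genes=DSB_GENES)])
    assert rho.iloc[0, 2] == pytest.approx(1.0)
    assert np.allclose(rho, rho.T)
    assert np.allclose(np.diag(rho), 1.0)


def test_spearman_reversed_ranks():
    x = np.column_stack([np.arange(1, 18), np.arange(17, 0, -1)]).astype(float)
    _, rho = dsb_pca_spearman([_table(x, genes=DSB_GENES)])
    assert rho.iloc[0, 1] == pytest.approx(-1.0)


def test_pca_spearman_requires_shared_genes():
    a = _table(np.ones((17, 2)), genes=DSB_GENES)
    b = _table(np.ones((2, 2)), genes=["X1", "X2"])
    with pytest.raises(ValueError):
        dsb_pca_spearman([a, b])


def test_wilcoxon_exact_matches_enumeration_in_report(rng):
    # spot-check the bulk report against scipy's exact test on clean data
    x = np.ones((17, 8)) + rng.random((17, 8))
    rep = pairwise_pathway_tests(build_pathway_table(_table(x, genes=DSB_GENES)))
    means = (build_pathway_table(_table(x, genes=DSB_GENES))
             .groupby(["sample", "pathway"], observed=True)["value"].mean().unstack())
    for _, row in rep.iterrows():
        ref = sps.wilcoxon(means[row.pathway_a] - means[row.pathway_b],
                           method="exact")
        assert row.p_value == pytest.approx(ref.pvalue)
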