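"""End-to-end drivers chaining the modules into the three analyses.

These are the package's configuration-driven entry points: each runs a full
analysis (single-cell scoring along a lineage; cross-species bulk
comparison; synthetic-data emission), writes a TSV/JSON artifact bundle plus
a provenance record (config hash, seed, version) and returns the in-memory
results. They are plain functions meant to be called from Python sessions or
short scripts — see the examples/ directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from anndata import AnnData

from . import __version__
from .bulk import (BulkTable, build_pathway_table, dsb_pca_spearman, log_tpm,
                   pairwise_pathway_tests)
from .genesets import load_retinal_markers, map_symbol, symbol_map
from .scoring import PathwayScores, compare_scores, score_cell_cycle, score_dsb
from .sc import (QC_PRESETS, QCThresholds, annotate_clusters_overlap,
                 cluster_graph, compute_qc_metrics, embed_pca, filter_cells,
                 knn_graph, normalize_log, rank_markers_ttest, select_common_hvg)
from .simulate import SimConfig, simulate_sc_trajectory
from .trajectory import (bin_curve, diffusion_pseudotime, polyfit_curve,
                         select_root, subset_lineage)
from .bulk import quantile_normalize

__all__ = ["RunConfig", "run_sc_score", "run_species_compare", "write_bundle"]

log = logging.getLogger(__name__)

LINEAGE_LABELS = ("progenitor", "neuroblast", "cone", "rod")


@dataclass
class RunConfig:
    """Parameters of a driver run; unknown keys are rejected on load."""

    analysis: str = "sc-score"
    seed: int = 0
    species: str = "human"
    preset: str | None = None
    outdir: str | None = None
    params: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _provenance(config: Mapping[str, Any], seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "dsbscore_version": __version__,
        "config": json.loads(blob),
    }


def write_bundle(outdir: str | Path, tables: Mapping[str, pd.DataFrame],
                 reports: Mapping[str, Any], provenance: dict) -> list[Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in tables.items():
        p = out / f"{name}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        written.append(p)
    for name, obj in reports.items():
        p = out / f"{name}.json"
        p.write_text(json.dumps(obj, indent=2, default=_jsonable))
        written.append(p)
    p = out / "provenance.json"
    p.write_text(json.dumps(provenance, indent=2, default=_jsonable))
    written.append(p)
    return written


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _subset_scores(ps: PathwayScores, index: pd.Index) -> PathwayScores:
    return PathwayScores(ps.set_name, ps.scores.loc[index], ps.excluded.loc[index],
                         ps.genes_used, ps.n_members)


def run_sc_score(adata: AnnData | None = None, *, species: str = "human",
                 qc: QCThresholds | str | None = None,
                 n_hvg: int = 600, n_pcs: int = 40, k: int = 15,
                 resolution: float = 1.0, algorithm: str = "leiden",
                 n_bins: int = 20, poly_degree: int = 3, seed: int = 0,
                 lineage_labels=LINEAGE_LABELS,
                 sim_config: SimConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Full single-cell chain: QC → normalize → HVG → PCA → graph → cluster →
    annotate → DSB/cell-cycle scores → lineage pseudotime → trajectory curves.

    With no ``adata``, the default synthetic scene is generated (seeded).
    ``qc`` may be a :class:`QCThresholds`, a preset name (``e15_mouse``,
    ``organoid``) or None (no filtering beyond zero-count removal). Writes
    the artifact bundle to ``outdir`` when given; always returns the
    in-memory results.
    """
    cfg_record = {"analysis": "sc-score", "species": species, "qc": str(qc),
                  "n_hvg": n_hvg, "n_pcs": n_pcs, "k": k, "resolution": resolution,
                  "algorithm": algorithm, "n_bins": n_bins, "poly_degree": poly_degree,
                  "seed": seed}
    if adata is None:
        sim_config = sim_config or SimConfig(seed=seed, species=species)
        adata, _ = simulate_sc_trajectory(sim_config)
    if isinstance(qc, str):
        qc = QC_PRESETS[qc]
    adata = compute_qc_metrics(adata)
    adata = filter_cells(adata, qc if qc is not None else QCThresholds(min_umi=0))
    log.info("run_sc_score: %d cells after QC", adata.n_obs)
    adata = normalize_log(adata)
    hvg = select_common_hvg(adata, n_genes=n_hvg)
    coords, evr = embed_pca(adata, genes=hvg, n_pcs=n_pcs, seed=seed)
    adj = knn_graph(coords, k=k)
    clusters = cluster_graph(adj, resolution=resolution, seed=seed, algorithm=algorithm)
    adata.obs["cluster"] = pd.Categorical([str(c) for c in clusters])
    markers = rank_markers_ttest(adata, "cluster")
    annotation = annotate_clusters_overlap(markers, load_retinal_markers(species))
    adata.obs["cell_type"] = adata.obs["cluster"].map(
        {cl: a["label"] for cl, a in annotation.items()}).astype(str)

    dsb = score_dsb(adata, species)
    cc = score_cell_cycle(adata, species=species)

    present = [l for l in lineage_labels if l in set(adata.obs["cell_type"])]
    lineage = subset_lineage(adata, present, key="cell_type")
    coord_df = pd.DataFrame(coords, index=adata.obs_names)
    lin_coords = coord_df.loc[lineage.obs_names].to_numpy()
    within = (lineage.obs["cell_type"] == "progenitor") if "progenitor" in present else None
    root = select_root(lineage, "score_G2M", within=within)
    pt = diffusion_pseudotime(lin_coords, root=root, cell_ids=lineage.obs_names, k=k)
    lineage.obs["pseudotime"] = pt.pseudotime

    curves, fits = {}, {}
    for name, ps in dsb.items():
        cv = bin_curve(_subset_scores(ps, lineage.obs_names), pt, n_bins=n_bins)
        curves[name] = polyfit_curve(cv, degree=poly_degree)
        fits[name] = {"degree": poly_degree,
                      "coefficients": curves[name].coefficients,
                      "residual_ss": curves[name].residual_ss}

    comparisons = {}
    if {"cone", "rod"} <= set(adata.obs["cell_type"]):
        for name, ps in dsb.items():
            groups = []
            for ct in ("cone", "rod"):
                mask = (adata.obs["cell_type"] == ct) & (~ps.excluded)
                groups.append((ct, ps.scores[mask].to_numpy()))
            if all(len(v) >= 3 for _, v in groups):
                comparisons[name] = compare_scores(groups).to_dict()

    results = {
        "adata": adata, "lineage": lineage, "hvg": hvg,
        "explained_variance": evr, "markers": markers,
        "annotation": annotation, "scores": dsb, "cell_cycle": cc,
        "pseudotime": pt, "curves": curves, "comparisons": comparisons,
        "provenance": _provenance(cfg_record, seed),
    }
    if outdir is not None:
        cluster_tab = adata.obs.reset_index(names="barcode")[
            ["barcode", "batch", "cluster", "cell_type"]].assign(
            overlap_score=[annotation[c]["score"] for c in adata.obs["cluster"]])
        score_tab = adata.obs.reset_index(names="barcode")[
            ["barcode", "batch", "cluster", "cell_type",
             "score_NHEJ", "score_MMEJ", "score_HDR",
             "excluded_NHEJ", "excluded_MMEJ", "excluded_HDR"]]
        curve_tab = pd.concat([c.bins.assign(pathway=n) for n, c in curves.items()])
        pt_tab = lineage.obs.reset_index(names="barcode")[["barcode", "pseudotime"]]
        write_bundle(outdir,
                     {"clusters": cluster_tab, "scores": score_tab,
                      "curves": curve_tab, "pseudotime": pt_tab},
                     {"fits": fits, "comparisons": comparisons},
                     results["provenance"])
    return results


def run_species_compare(tables: list[BulkTable], *, seed: int = 0,
                        outdir: str | Path | None = None) -> dict:
    """Cross-species bulk comparison.

    Quantile-normalizes replicates within each species, log2-transforms,
    builds the pathway long table, runs the replicate-paired Wilcoxon
    contrasts per species, and computes the DSB-gene PCA + Spearman matrix
    across all samples (gene symbols are mapped to human nomenclature first
    so mouse tables join the panel). With a single species the pairwise test
    report is still produced; correlations always are.
    """
    cfg_record = {"analysis": "species-compare", "seed": seed,
                  "n_tables": len(tables),
                  "species": [str(t.meta["species"].iloc[0]) for t in tables]}
    processed, harmonized = [], []
    for t in tables:
        qn = quantile_normalize(t, grouping="species")
        lt = log_tpm(qn)
        processed.append(lt)
        sp = str(t.meta["species"].iloc[0])
        if sp in ("human", "mouse", "macaque", "squirrel") and sp != "human":
            m = symbol_map(sp, "human")
            expr = lt.expr.copy()
            expr.index = [map_symbol(g, m) for g in expr.index]
            harmonized.append(BulkTable(expr, lt.meta.copy(), scale=lt.scale,
                                        log_transformed=True))
        else:
            harmonized.append(lt)
    long_tab = pd.concat([build_pathway_table(t) for t in processed], ignore_index=True)
    counts = long_tab.groupby("species", observed=True)["sample"].nunique()
    testable = counts.index[counts >= 2]
    skipped = sorted(set(counts.index) - set(testable))
    if skipped:
        log.warning("run_species_compare: species %s have a single sample; "
                    "pairwise tests skipped for them", skipped)
    if len(testable):
        tests = pairwise_pathway_tests(long_tab[long_tab["species"].isin(testable)])
    else:
        tests = pd.DataFrame(columns=["species", "pathway_a", "pathway_b",
                                      "statistic", "p_value", "n_pairs",
                                      "method", "direction", "mean_a", "mean_b"])
    coords, spearman = dsb_pca_spearman(harmonized)
    results = {
        "long_table": long_tab, "tests": tests, "pca": coords,
        "spearman": spearman,
        "provenance": _provenance(cfg_record, seed),
    }
    if outdir is not None:
        write_bundle(outdir,
                     {"pathway_long": long_tab, "tests": tests,
                      "pca": coords.reset_index(names="sample"),
                      "spearman": spearman.reset_index(names="sample")},
                     {"test_report": {
                         "pairing": "replicate-level pathway means",
                         "tests": tests.to_dict(orient="records")}},
                     results["provenance"])
    return results
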