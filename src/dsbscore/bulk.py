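"""Bulk RNA-seq pathway comparisons.

Covers the three bulk analyses: pathway summaries along a differentiation
time course, cross-species pathway expression with replicate-paired Wilcoxon
signed-rank contrasts, and PCA + Spearman comparison of samples on the DSB
gene panel (e.g. adult retina vs stem-cell-derived neurons).

Conventions fixed for this module: bulk expression is log2(x+1)-transformed
(the single-cell side uses natural log1p); quantile normalization is applied
within a metadata group (species) before the log transform; ties everywhere
use average ranks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .genesets import GeneSet, load_dsb_sets
from .stats import WilcoxonResult, wilcoxon_signed_rank

__all__ = [
    "BulkTable",
    "log_tpm",
    "quantile_normalize",
    "build_pathway_table",
    "pairwise_pathway_tests",
    "timecourse_summary",
    "dsb_pca_spearman",
]

log = logging.getLogger(__name__)


@dataclass
class BulkTable:
    """Genes × samples expression with per-sample metadata.

    ``expr`` is a DataFrame indexed by gene symbol with sample columns;
    ``meta`` is indexed by sample with columns among ``species``,
    ``condition``, ``day``, ``replicate``. Values are non-negative (TPM or
    normalized counts; the scale is recorded, not inferred).
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "tpm"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.expr.columns]
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("bulk expression must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)


def log_tpm(t: BulkTable) -> BulkTable:
    """log2(x+1) transform; metadata unchanged."""
    if (t.expr.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return BulkTable(np.log2(t.expr + 1.0), t.meta.copy(), scale=t.scale,
                     log_transformed=True)


def _qn_columns(x: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of columns with tie averaging."""
    n, m = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)  # mean of rank-r values across samples
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # tied input values receive the mean of their mapped target values
        df = pd.Series(mapped).groupby(pd.Series(col)).transform("mean")
        out[:, j] = df.to_numpy()
    return out


def quantile_normalize(t: BulkTable, grouping: str = "species") -> BulkTable:
    """Quantile-normalize samples within each metadata group.

    Within a group, each sample's rank-r value is replaced by the mean of the
    rank-r values across the group's samples; tied values receive the mean of
    their tied targets. Groups of a single sample pass through with a warning.
    """
    expr = t.expr.copy().astype(float)
    groups = t.meta[grouping] if grouping in t.meta else pd.Series("all", index=t.meta.index)
    for g, samples in groups.groupby(groups, observed=True).groups.items():
        cols = list(samples)
        if len(cols) < 2:
            log.warning("quantile_normalize: group %r has a single sample, passed through", g)
            continue
        expr[cols] = _qn_columns(expr[cols].to_numpy())
    return BulkTable(expr, t.meta.copy(), scale=f"{t.scale}-qn",
                     log_transformed=t.log_transformed)


def build_pathway_table(t: BulkTable, sets: list[GeneSet] | None = None,
                        species: str | None = None) -> pd.DataFrame:
    """Long table of (species, sample, pathway, gene, value) for DSB genes.

    One row per (sample, present pathway gene); absent genes are logged. A
    pathway with zero genes present raises, naming species and pathway.
    """
    rows = []
    species_col = t.meta["species"] if "species" in t.meta else pd.Series(
        species or "unknown", index=t.meta.index)
    for sp in species_col.unique():
        samples = species_col.index[species_col == sp]
        use_sets = sets if sets is not None else load_dsb_sets(
            sp if sp in ("human", "mouse", "macaque", "squirrel") else "human")
        for gs in use_sets:
            present = [g for g in gs.symbols if g in t.expr.index]
            absent = set(gs.symbols) - set(present)
            if absent:
                log.info("build_pathway_table: %s/%s missing genes %s", sp, gs.name, sorted(absent))
            if not present:
                raise ValueError(f"no {gs.name} genes present for species {sp!r}")
            for s in samples:
                vals = t.expr.loc[present, s]
                for g, v in vals.items():
                    rows.append((sp, s, gs.name, g, float(v)))
    return pd.DataFrame(rows, columns=["species", "sample", "pathway", "gene", "value"])


def pairwise_pathway_tests(long_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-paired Wilcoxon signed-rank contrasts between pathways.

    Pathways have unequal gene counts, so the pairing unit is the
    replicate-level pathway mean: per sample and pathway, mean expression over
    the pathway's genes; then for each pathway pair within a species,
    a signed-rank test on the sample-paired means (exact enumeration for
    n ≤ 12, normal approximation above). Direction > 0 means the first
    pathway of the pair is higher.
    """
    means = (long_table.groupby(["species", "sample", "pathway"], observed=True)["value"]
             .mean().unstack("pathway"))
    rows = []
    for sp, tab in means.groupby(level="species", observed=True):
        if len(tab) < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 replicates")
        for a, b in itertools.combinations(tab.columns, 2):
            r: WilcoxonResult = wilcoxon_signed_rank(tab[a].to_numpy(), tab[b].to_numpy())
            rows.append({
                "species": sp, "pathway_a": a, "pathway_b": b,
                "statistic": r.statistic, "p_value": r.p_value,
                "n_pairs": r.n_used, "method": r.method,
                "direction": r.direction,
                "mean_a": float(tab[a].mean()), "mean_b": float(tab[b].mean()),
            })
    return pd.DataFrame(rows)


def timecourse_summary(t: BulkTable, sets: list[GeneSet]) -> pd.DataFrame:
    """Per time point and gene set: mean expression and normal 95% CI.

    The mean pools set genes × replicates at each time point. Time points
    with a single replicate still report a CI over the gene spread but are
    flagged in ``single_replicate``.
    """
    if "day" not in t.meta:
        raise ValueError("time metadata ('day') required")
    rows = []
    for day, samples in t.meta.groupby("day", observed=True).groups.items():
        cols = list(samples)
        for gs in sets:
            present = [g for g in gs.symbols if g in t.expr.index]
            if not present:
                continue
            vals = t.expr.loc[present, cols].to_numpy().ravel()
            mean = float(vals.mean())
            ci = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            rows.append({"day": day, "set": gs.name, "n_values": vals.size,
                         "mean": mean, "ci_half": float(ci),
                         "single_replicate": len(cols) == 1})
    return pd.DataFrame(rows).sort_values(["set", "day"]).reset_index(drop=True)


def dsb_pca_spearman(tables: list[BulkTable], genes: list[str] | None = None,
                     n_pcs: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of samples on the shared DSB gene panel plus pairwise Spearman.

    Samples from all tables are merged on the genes common to every table
    (default: the union of the three curated human DSB sets); zero-variance
    genes are dropped with a log entry. Returns ``(coords, spearman)`` —
    sample × PC coordinates with explained variance in ``coords.attrs`` and
    the full sample × sample Spearman rank-correlation matrix (average ranks
    for ties).
    """
    if genes is None:
        genes = [g for gs in load_dsb_sets("human") for g in gs.symbols]
    shared = [g for g in genes if all(g in t.expr.index for t in tables)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared DSB genes across tables")
    merged = pd.concat([t.expr.loc[shared] for t in tables], axis=1)
    var = merged.var(axis=1)
    dropped = var.index[var == 0]
    if len(dropped):
        log.info("dsb_pca_spearman: dropping zero-variance genes %s", list(dropped))
        merged = merged.drop(index=dropped)
    x = merged.to_numpy().T  # samples × genes
    if x.shape[0] == 1:  # degenerate single-sample input
        coords = pd.DataFrame(np.zeros((1, 1)), index=merged.columns, columns=["PC1"])
        coords.attrs["explained_variance_ratio"] = np.array([0.0])
        return coords, pd.DataFrame([[1.0]], index=merged.columns, columns=merged.columns)
    n_pcs = max(1, min(n_pcs, min(x.shape) - 1))
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pd.DataFrame(pca.fit_transform(x), index=merged.columns,
                          columns=[f"PC{i + 1}" for i in range(n_pcs)])
    coords.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    m = merged.shape[1]
    rho = sps.spearmanr(merged.to_numpy(), axis=0)[0]
    if m == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    spearman = pd.DataFrame(rho, index=merged.columns, columns=merged.columns)
    return coords, spearman
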