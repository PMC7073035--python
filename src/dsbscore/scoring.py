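"""Per-cell (and per-sample) pathway activity scores.

A pathway score is the arithmetic mean of RAW UMI counts over the curated set
genes present in the panel. Dropout-heavy single-cell data yields cells with
all set genes at zero — a score of exactly 0 — and such cells are flagged
``excluded`` and ignored in downstream comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .genesets import GeneSet, load_cell_cycle_sets, load_dsb_sets
from .stats import GroupComparison, compare_scores  # re-exported for convenience

__all__ = [
    "PathwayScores",
    "MissingGeneSetError",
    "score_gene_set",
    "score_dsb",
    "score_cell_cycle",
    "compare_scores",
    "GroupComparison",
]

log = logging.getLogger(__name__)


class MissingGeneSetError(KeyError):
    """No member of a gene set is present in the expression panel."""


@dataclass
class PathwayScores:
    """Scores of one gene set across cells/samples.

    ``scores[i] == 0`` iff all present set genes are zero in cell i; those
    entries carry ``excluded=True`` and must not enter group comparisons.
    """

    set_name: str
    scores: pd.Series  # float, indexed by cell/sample id
    excluded: pd.Series  # bool, same index
    genes_used: list[str]
    n_members: int  # curated set size (incl. members absent from the panel)

    @property
    def kept(self) -> pd.Series:
        """Scores with zero-score cells removed."""
        return self.scores[~self.excluded]

    def __len__(self) -> int:
        return len(self.scores)


def _raw_matrix(adata: AnnData, layer: str | None):
    x = adata.layers[layer] if layer else adata.X
    return x


def score_gene_set(adata: AnnData, gene_set: GeneSet, layer: str | None = None) -> PathwayScores:
    """Mean raw count over the set genes present in the panel, per cell.

    Members absent from the panel are dropped from the denominator (panel
    coverage varies between datasets and absence is not evidence of
    inactivity); the genes actually used are recorded in the result. Matching
    is by exact symbol in the species' nomenclature.
    """
    present = [g for g in gene_set.symbols if g in adata.var_names]
    if not present:
        raise MissingGeneSetError(
            f"no member of gene set {gene_set.name!r} found in the panel")
    if len(present) < len(gene_set):
        log.info("gene set %s: %d/%d members present in panel",
                 gene_set.name, len(present), len(gene_set))
    sub = _raw_matrix(adata[:, present], layer)
    # integer sum then a single division: exact agreement with loop arithmetic
    if sparse.issparse(sub):
        sums = np.asarray(sub.sum(axis=1)).ravel()
    else:
        sums = np.asarray(sub).sum(axis=1)
    vals = sums / len(present)
    scores = pd.Series(vals, index=adata.obs_names, name=gene_set.name)
    return PathwayScores(
        set_name=gene_set.name,
        scores=scores,
        excluded=scores == 0,
        genes_used=present,
        n_members=len(gene_set),
    )


def score_dsb(adata: AnnData, species: str = "human",
              attach: bool = True) -> dict[str, PathwayScores]:
    """Score the three DSB repair pathways (NHEJ, MMEJ, HDR) for every cell.

    With ``attach=True`` the scores and exclusion flags are also written to
    ``adata.obs`` as ``score_<PATHWAY>`` / ``excluded_<PATHWAY>`` columns.
    """
    out = {}
    for gs in load_dsb_sets(species):
        ps = score_gene_set(adata, gs)
        out[gs.name] = ps
        if attach:
            adata.obs[f"score_{gs.name}"] = ps.scores
            adata.obs[f"excluded_{gs.name}"] = ps.excluded
    return out


def score_cell_cycle(adata: AnnData, sets: list[GeneSet] | None = None,
                     species: str = "human", attach: bool = True) -> dict[str, PathwayScores]:
    """Score cell-cycle phase sets (default packaged G2M/S stand-ins)."""
    sets = sets if sets is not None else load_cell_cycle_sets(species)
    out = {}
    for gs in sets:
        ps = score_gene_set(adata, gs)
        out[gs.name] = ps
        if attach:
            adata.obs[f"score_{gs.name}"] = ps.scores
    return out
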