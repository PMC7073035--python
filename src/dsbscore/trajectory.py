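"""Diffusion pseudotime ordering and pathway-score trajectory curves.

Cells on a differentiation lineage are ordered by a diffusion-map distance
from a root cell (default: the most strongly G2/M-cycling progenitor), then
pathway scores are summarized along pseudotime as equal-count bin means with
95% confidence bands and an optional polynomial fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .scoring import PathwayScores

__all__ = [
    "PseudotimeResult",
    "TrajectoryCurve",
    "subset_lineage",
    "select_root",
    "diffusion_pseudotime",
    "bin_curve",
    "polyfit_curve",
]

log = logging.getLogger(__name__)


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series  # unitless >= 0; inf for cells disconnected from the root
    root: str  # cell id
    n_comps: int
    eigenvalues: np.ndarray  # nontrivial eigenvalues used


@dataclass
class TrajectoryCurve:
    """Binned pseudotime summary of one score, plus optional polynomial fit."""

    pathway: str
    bins: pd.DataFrame  # columns: bin, midpoint, n, mean, ci_half, ci_lo, ci_hi
    coefficients: np.ndarray | None = None  # ascending order; None until fitted
    degree: int | None = None
    residual_ss: float | None = None


def subset_lineage(adata: AnnData, keep: list[str], key: str = "cell_type") -> AnnData:
    """Row-subset to the given cluster/cell-type labels, preserving layers."""
    labels = adata.obs[key].astype(str)
    missing = set(map(str, keep)) - set(labels.unique())
    if missing:
        raise KeyError(f"labels not present: {sorted(missing)}")
    mask = labels.isin([str(k) for k in keep]).to_numpy()
    if not mask.any():
        raise ValueError("lineage subset is empty")
    return adata[mask].copy()


def select_root(adata: AnnData, criterion: str = "score_G2M",
                within: pd.Series | np.ndarray | None = None) -> str:
    """Cell id with the maximal criterion score, tie-broken by barcode order.

    ``within`` optionally restricts the search (boolean mask over cells),
    e.g. to the progenitor cluster. The default criterion is the G2/M
    cell-cycle score: the most actively cycling progenitor anchors pseudotime
    zero at the start of differentiation.
    """
    if criterion not in adata.obs:
        raise KeyError(f"criterion {criterion!r} not computed")
    obs = adata.obs
    if within is not None:
        obs = obs[np.asarray(within, dtype=bool)]
        if obs.empty:
            raise ValueError("root restriction mask is empty")
    vals = obs[criterion]
    best = vals.max()
    candidates = sorted(vals.index[vals == best])
    return candidates[0]


def _dpt_from_coords(coords: np.ndarray, k: int, n_comps: int, root_idx: int):
    n = coords.shape[0]
    if n_comps < 2:
        raise ValueError("n_comps must be >= 2")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # locally adaptive Gaussian bandwidth: distance to the ceil(k/2)-th neighbor
    sigma = dist[:, int(np.ceil(k / 2))]
    sigma = np.maximum(sigma, 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    w = np.exp(-(d ** 2) / (sigma[rows] * sigma[cols]))
    wmat = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    wmat = wmat.maximum(wmat.T)

    n_cc, cc = connected_components(wmat, directed=False)
    comp = cc[root_idx]
    in_comp = cc == comp
    if n_cc > 1:
        log.warning("diffusion_pseudotime: %d cells disconnected from the root",
                    int((~in_comp).sum()))
    sub = wmat[in_comp][:, in_comp].toarray()
    m = sub.shape[0]
    # density normalization (alpha = 1) removes sampling-density bias
    q = sub.sum(axis=1)
    sub = sub / np.outer(q, q)
    d1 = sub.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    sym = sub * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary eigenvector (lambda = 1)
    lam = evals[1:n_comps + 1]
    psi = evecs[:, 1:n_comps + 1] * inv_sqrt[:, None]
    lam = np.clip(lam, None, 1 - 1e-10)
    scaled = psi * (lam / (1 - lam))[None, :]
    root_sub = int(np.where(np.flatnonzero(in_comp) == root_idx)[0][0])
    pt_sub = np.linalg.norm(scaled - scaled[root_sub], axis=1)
    pt = np.full(n, np.inf)
    pt[in_comp] = pt_sub
    return pt, lam


def diffusion_pseudotime(coords: np.ndarray, root: int | str,
                         cell_ids: pd.Index | None = None,
                         k: int = 15, n_comps: int = 10) -> PseudotimeResult:
    """Diffusion pseudotime from a root cell.

    A kNN similarity kernel with locally adaptive Gaussian bandwidth
    (per-cell bandwidth = distance to the ⌈k/2⌉-th neighbor) is density
    normalized and converted to a Markov transition matrix; the top
    ``n_comps`` nontrivial right eigenvectors ψ_i with eigenvalues λ_i define
    coordinates scaled by λ_i/(1−λ_i), and pseudotime is the Euclidean
    distance from the root in that space. Cells disconnected from the root's
    graph component receive infinite pseudotime and are excluded from curves.

    ``root`` may be an integer position or (with ``cell_ids``) a cell id.
    """
    coords = np.asarray(coords, dtype=float)
    if cell_ids is None:
        cell_ids = pd.Index([str(i) for i in range(coords.shape[0])])
    if isinstance(root, str):
        root_idx = int(cell_ids.get_loc(root))
    else:
        root_idx = int(root)
    if not 0 <= root_idx < coords.shape[0]:
        raise IndexError("root outside data")
    pt, lam = _dpt_from_coords(coords, k=k, n_comps=n_comps, root_idx=root_idx)
    return PseudotimeResult(
        pseudotime=pd.Series(pt, index=cell_ids, name="pseudotime"),
        root=str(cell_ids[root_idx]), n_comps=len(lam), eigenvalues=lam,
    )


def bin_curve(scores: PathwayScores, pt: PseudotimeResult, n_bins: int = 20) -> TrajectoryCurve:
    """Equal-count pseudotime bins with mean and normal-approximation 95% CI.

    Zero-score (excluded) cells and cells with non-finite pseudotime are
    dropped before binning. Bins are formed on pseudotime rank so late,
    sparsely populated stretches keep stable CI widths. A bin with a single
    cell reports an undefined (NaN) CI.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    keep = (~scores.excluded) & np.isfinite(pt.pseudotime.reindex(scores.scores.index))
    vals = scores.scores[keep]
    t = pt.pseudotime.reindex(vals.index)
    order = np.argsort(t.to_numpy(), kind="stable")
    rows = []
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        if chunk.size == 0:
            continue
        v = vals.to_numpy()[chunk]
        mid = float(t.to_numpy()[chunk].mean())
        mean = float(v.mean())
        if chunk.size >= 2:
            ci = 1.96 * v.std(ddof=1) / np.sqrt(chunk.size)
        else:
            ci = np.nan
        rows.append({"bin": b, "midpoint": mid, "n": int(chunk.size),
                     "mean": mean, "ci_half": ci,
                     "ci_lo": mean - ci, "ci_hi": mean + ci})
    return TrajectoryCurve(pathway=scores.set_name, bins=pd.DataFrame(rows))


def polyfit_curve(curve: TrajectoryCurve, degree: int = 3) -> TrajectoryCurve:
    """Least-squares polynomial fit to (bin midpoint, bin mean).

    Coefficients are stored in ascending order; requires at least
    ``degree + 1`` bins with defined means.
    """
    tab = curve.bins.dropna(subset=["mean"])
    if len(tab) < degree + 1:
        raise ValueError(f"need >= {degree + 1} bins for a degree-{degree} fit")
    x = tab["midpoint"].to_numpy()
    y = tab["mean"].to_numpy()
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    curve.coefficients = coeffs
    curve.degree = degree
    curve.residual_ss = float((resid ** 2).sum())
    return curve
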