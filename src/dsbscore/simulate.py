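"""Synthetic single-cell and bulk datasets with known ground truth.

The generator emulates the statistical structure the analyses assume, so
every pipeline stage is testable without downloads:

* droplet-style UMI counts (negative binomial with gene-level dispersion,
  log-normal library size, Bernoulli dropout) along a progenitor →
  neuroblast → photoreceptor (cone/rod) trajectory;
* cell-cycle-coupled HDR expression (high while cycling, collapsing at
  cell-cycle exit), an intermediate MMEJ program and a flat NHEJ program,
  encoded as piecewise-linear amplitude schedules over true time;
* cluster-specific marker genes matching the packaged retinal reference
  sets, plus inert background genes and a few mitochondrial genes for QC;
* bulk time courses and multi-species replicate panels with the same
  pathway structure.

All randomness is driven by ``SimConfig.seed``; the same seed reproduces
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .bulk import BulkTable
from .genesets import load_cell_cycle_sets, load_dsb_sets, load_retinal_markers

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_sc_trajectory",
    "simulate_bulk_timecourse",
    "simulate_species_panel",
    "DEFAULT_SPECIES_PROFILES",
]

Knots = tuple[tuple[float, float], ...]


@dataclass
class SimConfig:
    """Generator parameters; defaults define the reference study conditions.

    ``t_exit`` is the true-time point of cell-cycle exit. Pathway amplitude
    schedules are piecewise-linear (time, multiplier) knots: HDR collapses at
    cycle exit with a mild pre-exit decline (the cycling fraction of the
    progenitor pool already falls before full exit), MMEJ settles at an
    intermediate level, NHEJ is flat. ``type_intervals`` places each cell
    type on true time; types sharing an identical interval (cone/rod) are
    exclusive terminal branches.
    """

    seed: int = 0
    species: str = "human"
    n_cells: Mapping[str, int] = field(default_factory=lambda: {
        "progenitor": 500, "neuroblast": 400, "cone": 300, "rod": 300})
    type_intervals: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "progenitor": (0.0, 0.45), "neuroblast": (0.45, 0.65),
        "cone": (0.65, 1.0), "rod": (0.65, 1.0)})
    t_exit: float = 0.4
    ramp: float = 0.04  # width of the marker-membership transition at type borders
    hdr_knots: Knots = ((0.0, 1.0), (0.4, 0.8), (0.6, 0.08), (1.0, 0.04))
    mmej_knots: Knots = ((0.0, 1.0), (0.4, 0.9), (0.6, 0.5), (1.0, 0.45))
    nhej_knots: Knots = ((0.0, 1.0), (1.0, 1.0))
    cycle_on: float = 1.0
    cycle_off: float = 0.05
    n_markers_per_type: int = 10
    marker_effect: float = 8.0
    marker_base: float = 0.5
    dsb_base_mean: float = 2.0
    cycle_base_mean: float = 1.5
    background_mean: float = 0.5
    n_background: int = 200
    n_mito: int = 5
    mito_mean: float = 0.3
    libsize_sigma: float = 0.3
    nb_dispersion: float = 4.0  # NB size r; var = mu + mu^2/r
    dropout: float = 0.1
    n_batches: int = 1
    batch_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.t_exit < 1:
            raise ValueError("t_exit must lie in (0, 1)")
        if not self.n_cells or any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("every cell type needs a positive cell count")
        for knots in (self.hdr_knots, self.mmej_knots, self.nhej_knots):
            if any(a < 0 for _, a in knots):
                raise ValueError("amplitude multipliers must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class SimTruth:
    """Per-cell/per-sample and per-gene generative ground truth."""

    obs: pd.DataFrame  # cells or samples: true time/type/batch/cycling, or multipliers
    var: pd.DataFrame  # genes: category, pathway, base mean
    config: dict


def _interp(t: np.ndarray, knots: Knots) -> np.ndarray:
    xs, ys = zip(*knots)
    return np.interp(t, xs, ys)


def _trapezoid(t: np.ndarray, a: float, b: float, r: float) -> np.ndarray:
    """Membership weight: 1 inside [a, b], linear ramps of width r outside."""
    r = max(r, 1e-9)
    up = np.clip((t - (a - r)) / r, 0.0, 1.0)
    down = np.clip(((b + r) - t) / r, 0.0, 1.0)
    return up * down


def _marker_symbols(cfg: SimConfig) -> dict[str, list[str]]:
    refs = {gs.name: gs.symbols for gs in load_retinal_markers(cfg.species)}
    out = {}
    for ct in cfg.n_cells:
        syms = refs.get(ct, [])[:cfg.n_markers_per_type]
        while len(syms) < cfg.n_markers_per_type:
            syms = syms + [f"MK-{ct.upper()}-{len(syms) + 1}"]
        out[ct] = syms
    return out


def simulate_sc_trajectory(cfg: SimConfig | None = None) -> tuple[AnnData, SimTruth]:
    """Simulate a single-cell differentiation scene with ground truth.

    Per cell a true time is drawn uniformly on its type's interval; each
    gene's expected count is ``library factor × gene base mean × amplitude``,
    where the amplitude is the pathway/cycle schedule at the cell's time or
    the marker membership weight of the cell's type. Counts are negative
    binomial, thinned by Bernoulli dropout. Deterministic given the seed.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    types, times = [], []
    for ct, n in cfg.n_cells.items():
        a, b = cfg.type_intervals[ct]
        types += [ct] * n
        times.append(rng.uniform(a, b, size=n))
    t = np.concatenate(times)
    types = np.array(types)
    n_cells = t.size
    cycling = t < cfg.t_exit

    # --- gene panel ---------------------------------------------------
    dsb_sets = load_dsb_sets(cfg.species)
    cc_sets = load_cell_cycle_sets(cfg.species)
    markers = _marker_symbols(cfg)
    names, category, pathway, base = [], [], [], []

    def _add(syms, cat, pw, mean):
        for s in syms:
            names.append(s)
            category.append(cat)
            pathway.append(pw)
            base.append(mean)

    for gs in dsb_sets:
        _add(gs.symbols, "dsb", gs.name, cfg.dsb_base_mean)
    for gs in cc_sets:
        _add(gs.symbols, "cell_cycle", gs.name, cfg.cycle_base_mean)
    for ct, syms in markers.items():
        _add(syms, f"marker:{ct}", "MARKER", cfg.marker_base)
    _add([f"MT-SIM{i + 1}" for i in range(cfg.n_mito)], "mito", "none", cfg.mito_mean)
    _add([f"BG{i + 1:04d}" for i in range(cfg.n_background)], "background", "none",
         cfg.background_mean)
    n_genes = len(names)
    mu_g = np.asarray(base) * rng.lognormal(0.0, 0.3, size=n_genes)

    # --- amplitude matrix ---------------------------------------------
    amp = np.ones((n_cells, n_genes))
    path_knots = {"HDR": cfg.hdr_knots, "MMEJ": cfg.mmej_knots, "NHEJ": cfg.nhej_knots}
    cat = np.asarray(category)
    pw = np.asarray(pathway)
    for name, knots in path_knots.items():
        amp[:, (cat == "dsb") & (pw == name)] = _interp(t, knots)[:, None]
    cyc_amp = np.where(cycling, cfg.cycle_on, cfg.cycle_off)
    amp[:, cat == "cell_cycle"] = cyc_amp[:, None]
    for ct in cfg.n_cells:
        a, b = cfg.type_intervals[ct]
        w = _trapezoid(t, a, b, cfg.ramp)
        # identical intervals mark exclusive terminal branches: a cone never
        # expresses rod markers however close in time
        for other, (oa, ob) in cfg.type_intervals.items():
            if other != ct and (oa, ob) == (a, b):
                w = np.where(types == other, 0.0, w)
        amp[:, cat == f"marker:{ct}"] = (1.0 + (cfg.marker_effect - 1.0) * w)[:, None]

    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_cells)
    batch = rng.integers(cfg.n_batches, size=n_cells)
    mean = lib[:, None] * mu_g[None, :] * amp
    if cfg.batch_sigma > 0:
        bfac = rng.lognormal(0.0, cfg.batch_sigma, size=(cfg.n_batches, n_genes))
        mean = mean * bfac[batch]

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)

    obs = pd.DataFrame({
        "true_time": t, "true_type": types, "cycling": cycling,
        "batch": pd.Categorical([f"batch{b}" for b in batch]),
    }, index=[f"cell_{i:05d}" for i in range(n_cells)])
    var = pd.DataFrame({"category": category, "pathway": pathway, "base_mean": mu_g},
                       index=pd.Index(names, name="gene"))
    adata = AnnData(X=sparse.csr_matrix(counts.astype(np.int64)),
                    obs=obs.copy(), var=var.copy())
    truth = SimTruth(obs=obs, var=var, config=_config_dict(cfg))
    return adata, truth


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["n_cells"] = dict(cfg.n_cells)
    d["type_intervals"] = {k: list(v) for k, v in cfg.type_intervals.items()}
    return d


def _maturation(day: np.ndarray, cycle_off_day: float, max_day: float,
                t_exit: float) -> np.ndarray:
    """Map calendar days onto schedule time: cycle exit lands on t_exit."""
    day = np.asarray(day, dtype=float)
    pre = t_exit * day / max(cycle_off_day, 1e-9)
    span = max(max_day - cycle_off_day, 1e-9)
    post = t_exit + (1 - t_exit) * (day - cycle_off_day) / span
    return np.clip(np.where(day < cycle_off_day, pre, post), 0.0, 1.0)


def simulate_bulk_timecourse(cfg: SimConfig | None = None,
                             time_points: Sequence[float] = (0, 2, 4, 7, 14),
                             replicates: int = 3,
                             cycle_off_day: float = 4.0,
                             noise_sigma: float = 0.15,
                             base_tpm: float = 50.0) -> tuple[BulkTable, SimTruth]:
    """Bulk TPM time course with the same pathway amplitude schedules.

    Calendar days map onto schedule time so that cell-cycle exit falls at
    ``cycle_off_day`` (default 4, matching a fast neuronal-induction model);
    per-gene replicate noise is multiplicative log-normal.
    """
    cfg = cfg or SimConfig()
    if len(time_points) < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(cfg.seed)
    dsb_sets = load_dsb_sets(cfg.species)
    g2m = [gs for gs in load_cell_cycle_sets(cfg.species) if gs.name == "G2M"][0]
    names, pathways = [], []
    for gs in dsb_sets:
        names += gs.symbols
        pathways += [gs.name] * len(gs)
    names += g2m.symbols
    pathways += ["G2M"] * len(g2m)
    n_bg = 100
    names += [f"BG{i + 1:04d}" for i in range(n_bg)]
    pathways += ["background"] * n_bg
    base = base_tpm * rng.lognormal(0.0, 0.5, size=len(names))

    knots = {"HDR": cfg.hdr_knots, "MMEJ": cfg.mmej_knots, "NHEJ": cfg.nhej_knots}
    days = np.asarray(sorted(time_points), dtype=float)
    u = _maturation(days, cycle_off_day, days.max(), cfg.t_exit)
    cols, meta_rows, data = [], [], []
    for day, ui in zip(days, u):
        amp = np.ones(len(names))
        for pwname, kn in knots.items():
            amp[np.asarray(pathways) == pwname] = _interp(np.array([ui]), kn)[0]
        amp[np.asarray(pathways) == "G2M"] = cfg.cycle_on if day < cycle_off_day else cfg.cycle_off
        for rep in range(1, replicates + 1):
            vals = base * amp * rng.lognormal(0.0, noise_sigma, size=len(names))
            sample = f"d{day:g}_r{rep}"
            cols.append(sample)
            data.append(vals)
            meta_rows.append({"sample": sample, "species": cfg.species,
                              "condition": "in vitro", "day": float(day),
                              "replicate": rep})
    expr = pd.DataFrame(np.column_stack(data), index=pd.Index(names, name="gene"),
                        columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth_obs = meta.assign(maturation=np.repeat(u, replicates))
    truth_var = pd.DataFrame({"pathway": pathways, "base_tpm": base},
                             index=pd.Index(names, name="gene"))
    table = BulkTable(expr, meta, scale="tpm")
    return table, SimTruth(obs=truth_obs, var=truth_var, config=_config_dict(cfg))


#: NHEJ-dominant profile for human/macaque/mouse retina; the squirrel-like
#: profile has NHEJ ≈ MMEJ (cone-dominated retina with divergent repair mix).
DEFAULT_SPECIES_PROFILES: dict[str, dict[str, float]] = {
    "human": {"NHEJ": 3.0, "MMEJ": 1.5, "HDR": 0.6},
    "macaque": {"NHEJ": 3.0, "MMEJ": 1.5, "HDR": 0.6},
    "mouse": {"NHEJ": 3.0, "MMEJ": 1.5, "HDR": 0.6},
    "squirrel": {"NHEJ": 1.8, "MMEJ": 1.8, "HDR": 0.6},
}


def simulate_species_panel(cfg: SimConfig | None = None,
                           species: Sequence[str] = ("human", "macaque", "mouse", "squirrel"),
                           replicates: int = 6,
                           profiles: Mapping[str, Mapping[str, float]] | None = None,
                           noise_sigma: float = 0.2,
                           base_tpm: float = 50.0) -> tuple[list[BulkTable], SimTruth]:
    """Adult-retina replicate panels for several species.

    Each species gets the 17 curated DSB genes (species nomenclature) plus
    background genes. Gene baselines are rescaled so that each pathway's mean
    TPM equals exactly ``base_tpm × profile[pathway]`` — replicate noise is
    then the only source of pathway contrast under an equal profile, which
    keeps equal-profile contrasts (squirrel NHEJ vs MMEJ) properly null.
    """
    cfg = cfg or SimConfig()
    if replicates < 2:
        raise ValueError("need >= 2 replicates per species")
    profiles = profiles or DEFAULT_SPECIES_PROFILES
    rng = np.random.default_rng(cfg.seed)
    tables, truth_rows = [], []
    for sp in species:
        prof = profiles.get(sp, DEFAULT_SPECIES_PROFILES["human"])
        sets = load_dsb_sets(sp if sp in ("human", "mouse", "macaque", "squirrel") else "human")
        names, pathways, base = [], [], []
        for gs in sets:
            syms = gs.symbols
            b = rng.lognormal(0.0, 0.5, size=len(syms))
            b = b / b.mean() * base_tpm * prof[gs.name]  # exact pathway mean
            names += syms
            pathways += [gs.name] * len(syms)
            base += list(b)
        n_bg = 50
        names += [f"BG{i + 1:04d}" for i in range(n_bg)]
        pathways += ["background"] * n_bg
        base += list(base_tpm * rng.lognormal(0.0, 0.5, size=n_bg))
        base = np.asarray(base)
        cols, data, metas = [], [], []
        for rep in range(1, replicates + 1):
            vals = base * rng.lognormal(0.0, noise_sigma, size=base.size)
            sample = f"{sp}_r{rep}"
            cols.append(sample)
            data.append(vals)
            metas.append({"sample": sample, "species": sp, "condition": "in vivo retina",
                          "day": np.nan, "replicate": rep})
        expr = pd.DataFrame(np.column_stack(data), index=pd.Index(names, name="gene"),
                            columns=cols)
        meta = pd.DataFrame(metas).set_index("sample")
        tables.append(BulkTable(expr, meta, scale="tpm"))
        for pwname, mult in prof.items():
            truth_rows.append({"species": sp, "pathway": pwname,
                               "mean_tpm": base_tpm * mult})
    truth = SimTruth(obs=pd.DataFrame(truth_rows), var=pd.DataFrame(), config=_config_dict(cfg))
    return tables, truth
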