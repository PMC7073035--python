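"""Curated gene sets for DNA double-strand-break (DSB) repair pathway scoring.

Three pathways compete for a DSB in mammalian cells and each leaves a distinct
transcriptomic footprint:

* **NHEJ** (non-homologous end joining) — template-free ligation, active in all
  cell-cycle phases; initiated by end protection (Ku70/Ku80, 53BP1, WRN).
* **MMEJ** (microhomology-mediated end joining, a-EJ) — requires initial end
  resection (CtIP + MRN complex) and PARP1 binding.
* **HDR** (homology-directed repair) — high-fidelity, sister-chromatid templated
  repair restricted to S/G2; extended resection (EXO1, BLM) with RPA binding
  can also route the break to single-strand annealing (SSA).

The curated pathway membership shipped here assigns 4 genes to NHEJ, 5 to MMEJ
and 8 to HDR (RPA1/RPA2 are kept inside HDR with role ``SSA``). Auxiliary sets
(cell-cycle phase programs, retinal cell-type markers) support cluster
annotation and cell-cycle scoring; the shipped cell-cycle and retinal-marker
lists are documented stand-ins and are user-replaceable via :func:`read_gmt`
or :func:`read_json_sets`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GeneSet",
    "SymbolMap",
    "UnsupportedSpeciesError",
    "load_dsb_sets",
    "load_cell_cycle_sets",
    "load_retinal_markers",
    "symbol_map",
    "map_symbol",
    "read_gmt",
    "read_json_sets",
]

SUPPORTED_SPECIES = ("human", "mouse", "macaque", "squirrel")

PATHWAYS = ("NHEJ", "MMEJ", "HDR")


class UnsupportedSpeciesError(ValueError):
    """Raised when a species has no packaged nomenclature rules."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene list with pathway and per-gene functional role.

    ``members`` is an ordered tuple of ``(symbol, role)``; symbols are unique
    within a set. ``aliases`` records protein-name parentheticals (Ku80, CtIP)
    as metadata only — they are never used for expression-matrix lookup.
    """

    name: str
    pathway: str  # NHEJ | MMEJ | HDR | CELL_CYCLE | MARKER
    species: str
    members: tuple[tuple[str, str], ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        syms = [s for s, _ in self.members]
        if len(set(syms)) != len(syms):
            raise ValueError(f"duplicate symbols in gene set {self.name!r}")

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return any(s == symbol for s, _ in self.members)

    def role_of(self, symbol: str) -> str:
        for s, r in self.members:
            if s == symbol:
                return r
        raise KeyError(symbol)


@dataclass(frozen=True)
class SymbolMap:
    """Cross-species gene-symbol renaming.

    Explicit ``overrides`` take precedence; otherwise ``default_rule`` applies:

    * ``identity`` — symbol unchanged (human↔macaque/squirrel, whose bulk
      tables use human-style upper-case symbols);
    * ``title`` — mouse nomenclature, first letter upper rest lower
      (``BRCA1`` → ``Brca1``);
    * ``upper`` — back-map from mouse to upper-case human style.
    """

    source: str
    target: str
    overrides: Mapping[str, str] = field(default_factory=dict)
    default_rule: str = "identity"

    def __call__(self, symbol: str) -> str:
        return map_symbol(symbol, self)


def map_symbol(symbol: str, m: SymbolMap) -> str:
    """Rename *symbol* from ``m.source`` to ``m.target`` nomenclature."""
    if not symbol:
        raise ValueError("empty gene symbol")
    if symbol in m.overrides:
        return m.overrides[symbol]
    if m.default_rule == "identity":
        return symbol
    if m.default_rule == "title":
        return symbol[0].upper() + symbol[1:].lower()
    if m.default_rule == "upper":
        return symbol.upper()
    raise ValueError(f"unknown default rule {m.default_rule!r}")


def _resource() -> dict:
    with resources.files("dsbscore.data").joinpath("gene_sets.json").open() as fh:
        return json.load(fh)


def symbol_map(source: str, target: str) -> SymbolMap:
    """Build the packaged :class:`SymbolMap` between two supported species."""
    for sp in (source, target):
        if sp not in SUPPORTED_SPECIES:
            raise UnsupportedSpeciesError(f"unsupported species: {sp!r}")
    if source == target:
        return SymbolMap(source, target)
    data = _resource()
    if target == "mouse":
        return SymbolMap(source, target, overrides=dict(data["mouse_overrides"]),
                         default_rule="title")
    if source == "mouse":
        inverse = {v: k for k, v in data["mouse_overrides"].items()}
        return SymbolMap(source, target, overrides=inverse, default_rule="upper")
    # macaque / squirrel tables use human-style symbols; no ortholog inference
    return SymbolMap(source, target)


def load_dsb_sets(species: str = "human") -> list[GeneSet]:
    """Load the three curated DSB-repair pathway sets (NHEJ, MMEJ, HDR).

    Symbols are rendered in the species' nomenclature (mouse gets title-case
    plus the two true divergences Trp53bp1 and Mre11a).
    """
    if species not in SUPPORTED_SPECIES:
        raise UnsupportedSpeciesError(f"unsupported species: {species!r}")
    data = _resource()
    m = symbol_map("human", species)
    aliases = data["protein_aliases"]
    out = []
    for pathway in PATHWAYS:
        members = tuple((map_symbol(sym, m), role) for sym, role in data["dsb"][pathway])
        al = {map_symbol(s, m): a for s, a in aliases.items() if any(s == h for h, _ in data["dsb"][pathway])}
        out.append(GeneSet(name=pathway, pathway=pathway, species=species,
                           members=members, aliases=al))
    return out


def load_cell_cycle_sets(species: str = "human") -> list[GeneSet]:
    """Load stand-in cell-cycle phase sets (G2M top-20-style, S).

    The published analyses scored externally curated cell-cycle lists that are
    not redistributed here; these shipped defaults are commonly used phase
    markers and should be replaced with the user's preferred lists when exact
    correspondence matters.
    """
    if species not in SUPPORTED_SPECIES:
        raise UnsupportedSpeciesError(f"unsupported species: {species!r}")
    data = _resource()
    m = symbol_map("human", species)
    return [
        GeneSet(name=phase, pathway="CELL_CYCLE", species=species,
                members=tuple((map_symbol(s, m), "none") for s in syms))
        for phase, syms in data["cell_cycle"].items()
    ]


def load_retinal_markers(species: str = "human") -> list[GeneSet]:
    """Stand-in canonical retinal cell-type marker sets for cluster annotation."""
    if species not in SUPPORTED_SPECIES:
        raise UnsupportedSpeciesError(f"unsupported species: {species!r}")
    data = _resource()
    m = symbol_map("human", species)
    return [
        GeneSet(name=ct, pathway="MARKER", species=species,
                members=tuple((map_symbol(s, m), "none") for s in syms))
        for ct, syms in data["retinal_markers"].items()
    ]


def read_gmt(path: str | Path, species: str = "human",
             pathway: str = "MARKER") -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: name, description, symbols...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *symbols = fields
        sets.append(GeneSet(name=name, pathway=pathway, species=species,
                            members=tuple((s, "none") for s in symbols if s)))
    return sets


def read_json_sets(path: str | Path, species: str = "human") -> list[GeneSet]:
    """Read gene sets from the packaged JSON dialect.

    Accepts ``{"name": ["SYM", ...]}`` or ``{"name": [["SYM", "role"], ...]}``,
    optionally nested one level under a pathway key.
    """
    raw = json.loads(Path(path).read_text())
    out: list[GeneSet] = []

    def _members(entries: Iterable) -> tuple[tuple[str, str], ...]:
        mem = []
        for e in entries:
            if isinstance(e, str):
                mem.append((e, "none"))
            else:
                sym, role = e
                mem.append((sym, role))
        return tuple(mem)

    for name, val in raw.items():
        if isinstance(val, dict):
            for sub, entries in val.items():
                out.append(GeneSet(name=sub, pathway=name, species=species,
                                   members=_members(entries)))
        else:
            out.append(GeneSet(name=name, pathway="MARKER", species=species,
                               members=_members(val)))
    return out
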