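"""Catalog data model, file I/O, name normalization and validation.

A :class:`Catalog` bundles five record collections — herbs, compounds,
compound–target interactions, target proteins, and target–pathway
memberships — with referential integrity between them.  Identity
conventions follow common practice for this kind of data:

* compounds are identified by PubChem CID when known and by their
  normalized name otherwise (see :func:`normalize_compound_name`);
* target proteins are identified by their numeric KEGG ``hsa`` gene id,
  never by protein name — distinct genes may share a printed name;
* pathways are identified by one canonical KEGG pathway name each.

The module also ships a curated fixture: the post-screening catalog of 20
medicinal herbs used in traditional East-Asian practice for alopecia,
with 77 compounds, 25 target proteins and 54 KEGG pathways
(:func:`load_fixture`).  Fixture compounds are ``prescreened`` — their OB/DL
values and interaction prediction scores are not part of the record — so
the fixture supports counting analyses but not score-weighted centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml

from herbnet.errors import IntegrityError, SchemaError

__all__ = [
    "HerbRecord", "CompoundRecord", "TargetInteraction", "TargetRecord",
    "PathwayMembership", "Catalog", "ValidationReport",
    "normalize_compound_name", "load_catalog", "write_catalog",
    "validate_catalog", "load_fixture",
]

_TABLES: Mapping[str, tuple[str, ...]] = {
    "herbs": ("herb_id", "latin_name", "pinyin_name"),
    "compounds": ("compound_id", "name", "ob", "dl", "prescreened"),
    "herb_compound": ("herb_id", "compound_id"),
    "interactions": ("compound_id", "target_id", "score"),
    "targets": ("target_id", "description"),
    "pathways": ("pathway_name", "target_id"),
}


def normalize_compound_name(raw: str) -> str:
    """Canonicalize a compound name: casefold, trim, collapse whitespace.

    Idempotent and deterministic; raises ``ValueError`` on empty input.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("compound name must be non-empty")
    return " ".join(str(raw).casefold().split())


@dataclass(frozen=True)
class HerbRecord:
    herb_id: str
    latin_name: str = ""
    pinyin_name: str = ""
    compound_ids: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with optional ADME annotations.

    ``ob`` is on a percent scale, ``dl`` is a unitless index in [0, 1].
    ``prescreened`` marks records that already passed ADME screening
    upstream and therefore carry no OB/DL values.
    """

    compound_id: str
    name: str
    ob: float | None = None
    dl: float | None = None
    prescreened: bool = False


@dataclass(frozen=True)
class TargetInteraction:
    """A compound–target edge; ``score`` is the target-prediction score.

    A ``None`` score marks a prescreened interaction (already past the
    score cutoff upstream); such edges support counting analyses only.
    """

    compound_id: str
    target_id: str
    score: float | None = None


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    description: str = ""


@dataclass(frozen=True)
class PathwayMembership:
    pathway_name: str
    target_id: str


@dataclass
class Catalog:
    """The five record collections with referential integrity.

    ``herbs``, ``compounds`` and ``targets`` are keyed by their ids;
    ``interactions`` by the (compound_id, target_id) pair; ``memberships``
    is a set of (pathway_name, target_id) records.
    """

    herbs: dict[str, HerbRecord] = field(default_factory=dict)
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    interactions: dict[tuple[str, str], TargetInteraction] = field(default_factory=dict)
    targets: dict[str, TargetRecord] = field(default_factory=dict)
    memberships: set[PathwayMembership] = field(default_factory=set)

    # -- convenience views -------------------------------------------------
    def pathway_names(self) -> set[str]:
        return {m.pathway_name for m in self.memberships}

    def herb_compound_counts(self) -> dict[str, int]:
        return {h: len(r.compound_ids) for h, r in self.herbs.items()}

    def interactions_of(self, compound_id: str) -> list[TargetInteraction]:
        return [i for i in self.interactions.values() if i.compound_id == compound_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return (self.herbs == other.herbs and self.compounds == other.compounds
                and self.interactions == other.interactions
                and self.targets == other.targets
                and self.memberships == other.memberships)


@dataclass
class ValidationReport:
    """Invariant violations found in a catalog; empty iff the catalog is valid."""

    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when clean
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_catalog(catalog: Catalog) -> ValidationReport:
    """Check every catalog invariant; violations are reported, not raised.

    Checked: referential integrity of herb→compound, interaction→compound,
    interaction→target and membership→target references; OB/DL presence for
    non-prescreened compounds; DL within [0, 1] and OB ≥ 0; positive
    interaction scores; non-empty pathway names.
    """
    v: list[str] = []
    for herb in catalog.herbs.values():
        for cid in sorted(herb.compound_ids):
            if cid not in catalog.compounds:
                v.append(f"herb {herb.herb_id!r} references unknown compound {cid!r}")
    for comp in catalog.compounds.values():
        if not comp.prescreened and (comp.ob is None or comp.dl is None):
            v.append(f"compound {comp.compound_id!r} is not prescreened but lacks OB/DL")
        if comp.ob is not None and comp.ob < 0:
            v.append(f"compound {comp.compound_id!r} has negative OB {comp.ob}")
        if comp.dl is not None and not (0.0 <= comp.dl <= 1.0):
            v.append(f"compound {comp.compound_id!r} has DL {comp.dl} outside [0,1]")
    for (cid, tid), inter in catalog.interactions.items():
        if cid not in catalog.compounds:
            v.append(f"interaction ({cid!r}, {tid!r}) references unknown compound")
        if tid not in catalog.targets:
            v.append(f"interaction ({cid!r}, {tid!r}) references unknown target")
        if inter.score is not None and inter.score <= 0:
            v.append(f"interaction ({cid!r}, {tid!r}) has non-positive score {inter.score}")
    for m in sorted(catalog.memberships, key=lambda m: (m.pathway_name, m.target_id)):
        if not m.pathway_name.strip():
            v.append(f"membership for target {m.target_id!r} has empty pathway name")
        if m.target_id not in catalog.targets:
            v.append(f"membership {m.pathway_name!r} references unknown target {m.target_id!r}")
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_float(value: object) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def _parse_bool(value: object) -> bool:
    return str(value).strip().lower() in {"true", "1", "yes"}


def _frames_to_catalog(frames: Mapping[str, pd.DataFrame]) -> Catalog:
    for name, cols in _TABLES.items():
        df = frames[name]
        for col in cols:
            if col not in df.columns:
                raise SchemaError(f"table {name!r} is missing required column {col!r}")
    cat = Catalog()
    for row in frames["compounds"].itertuples(index=False):
        cid = str(row.compound_id)
        cat.compounds[cid] = CompoundRecord(
            compound_id=cid,
            name=normalize_compound_name(row.name) if str(row.name).strip() else cid,
            ob=_parse_float(row.ob),
            dl=_parse_float(row.dl),
            prescreened=_parse_bool(row.prescreened),
        )
    herb_comp: dict[str, set[str]] = {}
    dangling: list[str] = []
    for row in frames["herb_compound"].itertuples(index=False):
        hid, cid = str(row.herb_id), str(row.compound_id)
        if cid not in cat.compounds:
            dangling.append(f"herb {hid!r} -> unknown compound {cid!r}")
        herb_comp.setdefault(hid, set()).add(cid)
    for row in frames["herbs"].itertuples(index=False):
        hid = str(row.herb_id)
        cat.herbs[hid] = HerbRecord(
            herb_id=hid,
            latin_name=str(row.latin_name),
            pinyin_name=str(row.pinyin_name),
            compound_ids=frozenset(herb_comp.get(hid, set())),
        )
    for hid in herb_comp:
        if hid not in cat.herbs:
            dangling.append(f"herb_compound row -> unknown herb {hid!r}")
    for row in frames["targets"].itertuples(index=False):
        tid = str(row.target_id)
        cat.targets[tid] = TargetRecord(target_id=tid, description=str(row.description))
    for row in frames["interactions"].itertuples(index=False):
        cid, tid = str(row.compound_id), str(row.target_id)
        if cid not in cat.compounds:
            dangling.append(f"interaction -> unknown compound {cid!r}")
        if tid not in cat.targets:
            dangling.append(f"interaction -> unknown target {tid!r}")
        cat.interactions[(cid, tid)] = TargetInteraction(
            compound_id=cid, target_id=tid, score=_parse_float(row.score))
    for row in frames["pathways"].itertuples(index=False):
        tid = str(row.target_id)
        if tid not in cat.targets:
            dangling.append(f"membership {row.pathway_name!r} -> unknown target {tid!r}")
        cat.memberships.add(PathwayMembership(str(row.pathway_name), tid))
    if dangling:
        raise IntegrityError("dangling references: " + "; ".join(sorted(dangling)))
    return cat


def load_catalog(path: str | Path,
                 format: Literal["tabular", "structured"] = "tabular") -> Catalog:
    """Load a catalog from disk.

    ``tabular``: *path* is a directory holding six UTF-8 tab-delimited
    files (herbs.tsv, compounds.tsv, herb_compound.tsv, interactions.tsv,
    targets.tsv, pathways.tsv) with header rows; empty string means absent.
    ``structured``: *path* is one YAML document carrying the same six
    record collections as lists of mappings.

    Raises :class:`SchemaError` for a missing column and
    :class:`IntegrityError` (listing the offenders) for dangling references.
    """
    path = Path(path)
    if format == "tabular":
        frames = {}
        for name in _TABLES:
            f = path / f"{name}.tsv"
            if not f.exists():
                raise SchemaError(f"missing table file {f}")
            frames[name] = pd.read_csv(f, sep="\t", dtype=str, keep_default_na=False)
        return _frames_to_catalog(frames)
    if format == "structured":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        frames = {}
        for name, cols in _TABLES.items():
            rows = doc.get(name, [])
            frames[name] = pd.DataFrame(rows, columns=cols, dtype=str).fillna("")
        return _frames_to_catalog(frames)
    raise ValueError(f"unknown catalog format {format!r}")


def _catalog_frames(cat: Catalog) -> dict[str, pd.DataFrame]:
    def fmt(x: float | None) -> str:
        return "" if x is None else repr(x)

    herbs = pd.DataFrame(
        [[h.herb_id, h.latin_name, h.pinyin_name]
         for h in sorted(cat.herbs.values(), key=lambda h: h.herb_id)],
        columns=list(_TABLES["herbs"]))
    compounds = pd.DataFrame(
        [[c.compound_id, c.name, fmt(c.ob), fmt(c.dl),
          "true" if c.prescreened else "false"]
         for c in sorted(cat.compounds.values(), key=lambda c: c.compound_id)],
        columns=list(_TABLES["compounds"]))
    herb_compound = pd.DataFrame(
        [[hid, cid] for hid in sorted(cat.herbs)
         for cid in sorted(cat.herbs[hid].compound_ids)],
        columns=list(_TABLES["herb_compound"]))
    interactions = pd.DataFrame(
        [[c, t, fmt(cat.interactions[(c, t)].score)]
         for c, t in sorted(cat.interactions)],
        columns=list(_TABLES["interactions"]))
    targets = pd.DataFrame(
        [[t.target_id, t.description]
         for t in sorted(cat.targets.values(), key=lambda t: t.target_id)],
        columns=list(_TABLES["targets"]))
    pathways = pd.DataFrame(
        sorted([m.pathway_name, m.target_id] for m in cat.memberships),
        columns=list(_TABLES["pathways"]))
    return {"herbs": herbs, "compounds": compounds, "herb_compound": herb_compound,
            "interactions": interactions, "targets": targets, "pathways": pathways}


def write_catalog(catalog: Catalog, path: str | Path,
                  format: Literal["tabular", "structured"] = "tabular") -> None:
    """Write a catalog; inverse of :func:`load_catalog` (round-trip safe)."""
    path = Path(path)
    frames = _catalog_frames(catalog)
    if format == "tabular":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(path / f"{name}.tsv", sep="\t", index=False,
                      lineterminator="\n")
        return
    if format == "structured":
        doc = {name: df.to_dict(orient="records") for name, df in frames.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
        return
    raise ValueError(f"unknown catalog format {format!r}")


def load_fixture() -> Catalog:
    """Load the packaged 20-herb alopecia catalog.

    A curated, name-canonicalized transcription of the published records
    for the 20 medicinal herbs: 77 distinct compounds (prescreened, no
    OB/DL), 100 score-absent compound–target edges over 25 KEGG ``hsa``
    targets, and 142 target–pathway memberships over 54 canonical KEGG
    pathway names.  Two spellings of the same pathway were merged to one
    canonical name during curation; compounds listed under two names
    (e.g. riboflavin and vitamin b2) remain distinct records, as printed.
    """
    root = resources.files("herbnet").joinpath("data/fixture")
    with resources.as_file(root) as p:
        return load_catalog(p, format="tabular")
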