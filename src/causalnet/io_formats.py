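"""Readers and writers for every flat-file dialect the pipeline touches.

All tabular dialects are TSV/CSV (delimiter chosen by extension: ``.tsv`` tab,
``.csv`` comma — never sniffed), UTF-8 encoded. Every reader validates the
required columns up front and raises :class:`FormatError` naming the missing
column; parsed row counts are logged. Writers emit deterministic column order
and row sort so outputs are diffable. Column schemas per dialect are documented
in ``docs/formats.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .causal_profile import AssayRecord, CompoundTargetRecord, MoACategory

logger = logging.getLogger("causalnet")


class FormatError(ValueError):
    """An input file violates its dialect's schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompoundGroupList:
    """Named list of compound identifiers (e.g. a toxic or non-toxic group)."""

    label: str
    compound_ids: list[str]

    def __post_init__(self):
        if not self.label:
            raise ValueError("group label must be non-empty")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("compound identifiers must be unique within a group")

    def __len__(self) -> int:
        return len(self.compound_ids)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in set(self.compound_ids)


@dataclass(frozen=True)
class ExpressionRecord:
    """Tissues in which one protein is expressed.

    Tissue names are stored case-preserved and compared case-insensitively.
    """

    protein_id: str
    tissues: frozenset[str]

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")

    def expressed_in(self, tissue: str) -> bool:
        needle = tissue.casefold()
        return any(t.casefold() == needle for t in self.tissues)


@dataclass(frozen=True)
class StringEdge:
    """Undirected protein-protein edge with a 0-1000 combined confidence score."""

    protein_a: str
    protein_b: str
    combined_score: int

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError("self-loop edges are not allowed")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"combined_score out of [0, 1000]: {self.combined_score}")


@dataclass(frozen=True)
class SignorRecord:
    """One raw causal-interaction row; non-protein rows are filtered downstream."""

    type_a: str
    id_a: str
    type_b: str
    id_b: str
    effect: str

    def __post_init__(self):
        if not self.id_a or not self.id_b:
            raise ValueError("entity identifiers must be non-empty")


@dataclass(frozen=True)
class Pathway:
    """A named gene set (GMT line)."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class MechanismRow:
    compound_id: str
    target_id: str
    action_type: str


@dataclass(frozen=True)
class IupharRow:
    compound_id: str
    target_id: str
    actions: str


@dataclass(frozen=True)
class DrugBankRow:
    compound_id: str
    target_id: str
    action: str


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _delimiter(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    logger.info("%s: parsed %d rows", path.name, len(df))
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_group_list(path: str | Path, label: str | None = None) -> CompoundGroupList:
    """Read a compound group list: one identifier per line, ``#`` comments allowed.

    Duplicates are dropped (order-preserving) with a warning; an empty file is
    an error. The group label defaults to the file stem.
    """
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    duplicates = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            duplicates += 1
            continue
        seen.add(token)
        ids.append(token)
    if not ids:
        raise FormatError(f"{path}: no compound identifiers found")
    if duplicates:
        logger.warning("%s: dropped %d duplicate identifiers", path.name, duplicates)
    logger.info("%s: %d compound identifiers", path.name, len(ids))
    return CompoundGroupList(label=label or path.stem, compound_ids=ids)


def read_chembl_mechanisms(path: str | Path) -> list[MechanismRow]:
    """Curated mechanism export: columns compound_id, target_id, action_type."""
    df = _read_table(path, ["compound_id", "target_id", "action_type"])
    return [
        MechanismRow(r.compound_id, r.target_id, r.action_type)
        for r in df.itertuples(index=False)
    ]


def read_iuphar_interactions(path: str | Path) -> list[IupharRow]:
    """Pharmacology interaction export: columns compound_id, target_id, actions."""
    df = _read_table(path, ["compound_id", "target_id", "actions"])
    return [
        IupharRow(r.compound_id, r.target_id, r.actions) for r in df.itertuples(index=False)
    ]


def read_drugbank_skim(path: str | Path) -> list[DrugBankRow]:
    """DrugBank-skim table: columns compound_id, target_id, action."""
    df = _read_table(path, ["compound_id", "target_id", "action"])
    return [
        DrugBankRow(r.compound_id, r.target_id, r.action) for r in df.itertuples(index=False)
    ]


def read_chembl_assays(path: str | Path) -> list[AssayRecord]:
    """Assay bioactivity export: compound_id, target_id, assay_description,
    pchembl_value (may be blank), activity_comment (may be blank)."""
    df = _read_table(
        path, ["compound_id", "target_id", "assay_description", "pchembl_value", "activity_comment"]
    )
    records = []
    for r in df.itertuples(index=False):
        pchembl = float(r.pchembl_value) if str(r.pchembl_value).strip() else None
        comment = r.activity_comment if str(r.activity_comment).strip() else None
        records.append(
            AssayRecord(
                compound_id=r.compound_id,
                target_id=r.target_id,
                assay_description=r.assay_description,
                pchembl=pchembl,
                activity_comment=comment,
            )
        )
    return records


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Protein->tissues table: columns protein_id, tissues (';'-separated)."""
    df = _read_table(path, ["protein_id", "tissues"])
    records = []
    for r in df.itertuples(index=False):
        tissues = frozenset(t.strip() for t in str(r.tissues).split(";") if t.strip())
        records.append(ExpressionRecord(protein_id=r.protein_id, tissues=tissues))
    return records


def read_string_edges(path: str | Path) -> list[StringEdge]:
    """Weighted edge list: columns protein_a, protein_b, combined_score (0-1000).

    Self-loop rows are dropped with a warning.
    """
    df = _read_table(path, ["protein_a", "protein_b", "combined_score"])
    edges = []
    self_loops = 0
    for r in df.itertuples(index=False):
        if r.protein_a == r.protein_b:
            self_loops += 1
            continue
        edges.append(StringEdge(r.protein_a, r.protein_b, int(r.combined_score)))
    if self_loops:
        logger.warning("%s: dropped %d self-loop edges", Path(path).name, self_loops)
    return edges


def read_signor_tsv(path: str | Path) -> list[SignorRecord]:
    """Causal interaction TSV: columns type_a, id_a, type_b, id_b, effect.

    No filtering happens here; non-protein rows are retained for downstream
    protein-protein selection.
    """
    df = _read_table(path, ["type_a", "id_a", "type_b", "id_b", "effect"])
    return [
        SignorRecord(r.type_a, r.id_a, r.type_b, r.id_b, r.effect)
        for r in df.itertuples(index=False)
    ]


def read_gmt(path: str | Path) -> list[Pathway]:
    """Standard GMT: per line ``name<TAB>description<TAB>member...``."""
    path = Path(path)
    pathways: list[Pathway] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        pathway_id, name = fields[0], fields[1]
        if pathway_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate pathway id {pathway_id!r}")
        seen.add(pathway_id)
        members = frozenset(m for m in fields[2:] if m)
        pathways.append(Pathway(pathway_id=pathway_id, name=name or pathway_id, members=members))
    logger.info("%s: %d pathways", path.name, len(pathways))
    return pathways


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Optional two-column protein_id -> gene_name display mapping."""
    df = _read_table(path, ["protein_id", "gene_name"])
    return dict(zip(df.protein_id, df.gene_name))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["compound_id", "target_id", "category", "source", "evidence"]


def write_profile_tsv(records: list[CompoundTargetRecord], path: str | Path) -> None:
    """Write a harmonized profile, sorted by (compound, target, category)."""
    rows = sorted(records, key=lambda r: (r.compound_id, r.target_id, int(r.category)))
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_id": r.target_id,
                "category": int(r.category),
                "source": r.source,
                "evidence": r.evidence,
            }
            for r in rows
        ],
        columns=PROFILE_COLUMNS,
    )
    df.to_csv(path, sep=_delimiter(Path(path)), index=False)


def read_profile_tsv(path: str | Path) -> list[CompoundTargetRecord]:
    """Read back a profile written by :func:`write_profile_tsv`."""
    df = _read_table(path, PROFILE_COLUMNS)
    return [
        CompoundTargetRecord(
            compound_id=r.compound_id,
            target_id=r.target_id,
            category=MoACategory(int(r.category)),
            source=r.source,
            evidence=r.evidence,
        )
        for r in df.itertuples(index=False)
    ]


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis result table as-is (caller fixes column/row order)."""
    df.to_csv(path, sep=_delimiter(Path(path)), index=False)


def write_network_graphml(graph: nx.Graph | nx.MultiDiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_edgelist_tsv(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Deterministic TSV mirror of the GraphML network output."""
    rows = []
    for a, b, data in graph.edges(data=True):
        rows.append(
            {
                "source": a,
                "target": b,
                "layer": data.get("layer", ""),
                "weight": data.get("weight", ""),
                "effect": data.get("effect", ""),
                "moi": data.get("moi", ""),
            }
        )
    df = pd.DataFrame(rows, columns=["source", "target", "layer", "weight", "effect", "moi"])
    df = df.sort_values(["layer", "source", "target", "effect"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
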