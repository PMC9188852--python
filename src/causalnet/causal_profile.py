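"""Harmonized causal drug->target profiles.

Heterogeneous sources (curated mechanism-of-action records, assay-level
bioactivity with free-text descriptions, interaction tables from different
pharmacology databases) are translated into a single four-level mode-of-action
coding per drug-protein pair:

    1  active, positive modulator
    2  active, negative modulator
    3  active, no directional information (1 and 2 are sub-groups of 3)
    4  inactive (tested together, no activity)

Curated vocabularies map exactly (after trimming and case-folding); assay
descriptions are mined with directional keywords combined with a pChEMBL
activity cutoff (pChEMBL 5 == 10 uM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("causalnet")

DEFAULT_PCHEMBL_CUTOFF = 5.0

#: activity-comment phrases. "not active"/"inactive" must be checked before
#: the bare "active" substring.
INCONCLUSIVE_COMMENT_PHRASES = ("inconclusive",)
INACTIVE_COMMENT_PHRASES = ("not active", "inactive")
ACTIVE_COMMENT_PHRASES = ("active",)


class MoACategory(IntEnum):
    """Mode-of-action category of a drug-protein (or protein-protein) relation."""

    POSITIVE = 1
    NEGATIVE = 2
    ACTIVE_UNSPECIFIED = 3
    INACTIVE = 4


class _ExcludedType:
    """Singleton marker for assay records removed as contradictory/uninformative."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "Excluded"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`annotate_assay` for data points dropped from the profile.
EXCLUDED = _ExcludedType()


class UnmappedTermError(KeyError):
    """A vocabulary term with no entry in the mapping table."""

    def __init__(self, term: str, vocabulary: str):
        super().__init__(term)
        self.term = term
        self.vocabulary = vocabulary

    def __str__(self) -> str:
        return f"unmapped {self.vocabulary} vocabulary term: {self.term!r}"


@dataclass(frozen=True)
class CompoundTargetRecord:
    """One harmonized causal drug->protein assertion."""

    compound_id: str
    target_id: str
    category: MoACategory
    source: str  # chembl_mechanism | drugbank | iuphar | chembl_assay
    evidence: str = ""

    def __post_init__(self):
        if not self.compound_id or not self.target_id:
            raise ValueError("compound_id and target_id must be non-empty")


@dataclass(frozen=True)
class AssayRecord:
    """Raw assay-level evidence awaiting categorization."""

    compound_id: str
    target_id: str
    assay_description: str = ""
    pchembl: float | None = None
    activity_comment: str | None = None

    def __post_init__(self):
        if self.pchembl is not None:
            if isinstance(self.pchembl, float) and math.isnan(self.pchembl):
                object.__setattr__(self, "pchembl", None)
            elif self.pchembl < 0:
                raise ValueError(f"pchembl must be >= 0, got {self.pchembl}")


@dataclass(frozen=True)
class KeywordRule:
    """A directional keyword mined from assay descriptions.

    ``exclusions`` are phrases whose co-occurrence in the description voids
    the match (e.g. "inactivation" contains "activation" but implies the
    opposite direction).
    """

    phrase: str
    category: MoACategory
    exclusions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.phrase:
            raise ValueError("keyword phrase must be non-empty")
        if self.category not in (MoACategory.POSITIVE, MoACategory.NEGATIVE):
            raise ValueError("keyword rules must be directional (category 1 or 2)")

    def matches(self, description: str) -> bool:
        text = description.casefold()
        if self.phrase.casefold() not in text:
            return False
        return not any(ex.casefold() in text for ex in self.exclusions)


# ---------------------------------------------------------------------------
# packaged vocabulary tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("causalnet.data").joinpath(name)


def _load_mapping(name: str, term_column: str) -> dict[str, MoACategory]:
    with resources.as_file(_data_path(name)) as path:
        df = pd.read_csv(path, sep="\t")
    mapping: dict[str, MoACategory] = {}
    for term, cat in zip(df[term_column], df["category"]):
        key = str(term).strip().casefold()
        if key in mapping:
            raise ValueError(f"duplicate term {term!r} in {name}")
        mapping[key] = MoACategory(int(cat))
    return mapping


def load_chembl_actions() -> dict[str, MoACategory]:
    """Packaged action_type -> category table for curated mechanism records."""
    return _load_mapping("chembl_actions.tsv", "action_type")


def load_iuphar_actions() -> dict[str, MoACategory]:
    """Packaged actions -> category table for pharmacology interaction records."""
    return _load_mapping("iuphar_actions.tsv", "actions")


def load_drugbank_actions() -> dict[str, MoACategory]:
    """Packaged action -> category table for the DrugBank-skim dialect."""
    return _load_mapping("drugbank_actions.tsv", "action")


def load_keyword_rules() -> list[KeywordRule]:
    """Packaged directional keyword rules for assay-description mining."""
    with resources.as_file(_data_path("assay_keywords.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    rules = []
    for row in df.itertuples(index=False):
        exclusions = frozenset()
        raw = getattr(row, "exclusions", None)
        if isinstance(raw, str) and raw.strip():
            exclusions = frozenset(p.strip() for p in raw.split("|") if p.strip())
        rules.append(
            KeywordRule(
                phrase=str(row.phrase),
                category=MoACategory(int(row.category)),
                exclusions=exclusions,
            )
        )
    return rules


# ---------------------------------------------------------------------------
# mapping operations
# ---------------------------------------------------------------------------


def _map_term(term: str, mapping: Mapping[str, MoACategory], vocabulary: str) -> MoACategory:
    key = str(term).strip().casefold()
    try:
        return mapping[key]
    except KeyError:
        raise UnmappedTermError(term, vocabulary) from None


def map_chembl_action(action_type: str, mapping: Mapping[str, MoACategory] | None = None) -> MoACategory:
    """Map a curated mechanism ``action_type`` (e.g. ``"AGONIST"``) to a category.

    Matching is exact after trimming and case-folding; an unknown term raises
    :class:`UnmappedTermError` rather than silently falling back to category 3.
    """
    return _map_term(action_type, mapping or load_chembl_actions(), "chembl action_type")


def map_iuphar_action(actions: str, mapping: Mapping[str, MoACategory] | None = None) -> MoACategory:
    """Map a pharmacology-database ``actions`` term (e.g. ``"Activation"``)."""
    return _map_term(actions, mapping or load_iuphar_actions(), "iuphar actions")


def map_drugbank_action(term: str, mapping: Mapping[str, MoACategory] | None = None) -> MoACategory:
    """Map a DrugBank-style action term (e.g. ``"inhibitor"``)."""
    return _map_term(term, mapping or load_drugbank_actions(), "drugbank action")


def _comment_implication(comment: str | None) -> str | None:
    """Classify an activity comment as 'inconclusive', 'inactive', 'active' or None."""
    if comment is None or not str(comment).strip():
        return None
    text = str(comment).casefold()
    if any(p in text for p in INCONCLUSIVE_COMMENT_PHRASES):
        return "inconclusive"
    if any(p in text for p in INACTIVE_COMMENT_PHRASES):
        return "inactive"
    if any(p in text for p in ACTIVE_COMMENT_PHRASES):
        return "active"
    return None


def annotate_assay(
    record: AssayRecord,
    rules: Sequence[KeywordRule] | None = None,
    active_cutoff: float = DEFAULT_PCHEMBL_CUTOFF,
) -> MoACategory | _ExcludedType:
    """Categorize one assay data point.

    Decision procedure:

    1. missing pChEMBL -> Excluded (activity cannot be established);
    2. pChEMBL >= cutoff but the activity comment implies inactive or
       inconclusive -> Excluded (contradiction);
    3. pChEMBL < cutoff but the comment implies active or inconclusive
       -> Excluded (contradiction);
    4. pChEMBL < cutoff -> category 4 (tested, not active);
    5. pChEMBL >= cutoff: case-insensitive keyword substring match on the
       description; a single direction -> that category; both directions
       matched after exclusion handling -> Excluded; no keyword -> category 3.
    """
    if rules is None:
        rules = load_keyword_rules()
    if record.pchembl is None:
        return EXCLUDED
    implication = _comment_implication(record.activity_comment)
    if implication == "inconclusive":
        return EXCLUDED
    active = record.pchembl >= active_cutoff
    if active and implication == "inactive":
        return EXCLUDED
    if not active:
        if implication == "active":
            return EXCLUDED
        return MoACategory.INACTIVE

    matched = {rule.category for rule in rules if rule.matches(record.assay_description)}
    if not matched:
        return MoACategory.ACTIVE_UNSPECIFIED
    if len(matched) == 1:
        return next(iter(matched))
    return EXCLUDED


def build_profile(
    mechanisms: Iterable[tuple[str, str, str]] = (),
    drugbank: Iterable[tuple[str, str, str]] = (),
    iuphar: Iterable[tuple[str, str, str]] = (),
    assays: Iterable[AssayRecord] = (),
    compound_filter: Iterable[str] | None = None,
    active_cutoff: float = DEFAULT_PCHEMBL_CUTOFF,
    chembl_mapping: Mapping[str, MoACategory] | None = None,
    drugbank_mapping: Mapping[str, MoACategory] | None = None,
    iuphar_mapping: Mapping[str, MoACategory] | None = None,
    keyword_rules: Sequence[KeywordRule] | None = None,
) -> list[CompoundTargetRecord]:
    """Union the per-source harmonized records into one causal profile.

    ``mechanisms``/``drugbank``/``iuphar`` rows are ``(compound_id, target_id,
    term)`` triples; ``assays`` are :class:`AssayRecord`. Records are restricted
    to compounds in ``compound_filter`` (when given) and deduplicated to unique
    ``(compound, target, category)`` triples with merged evidence strings.
    """
    allowed = None if compound_filter is None else set(compound_filter)
    chembl_mapping = chembl_mapping or load_chembl_actions()
    drugbank_mapping = drugbank_mapping or load_drugbank_actions()
    iuphar_mapping = iuphar_mapping or load_iuphar_actions()
    keyword_rules = keyword_rules if keyword_rules is not None else load_keyword_rules()

    merged: dict[tuple[str, str, MoACategory], dict[str, list[str]]] = {}
    counts = {"chembl_mechanism": 0, "drugbank": 0, "iuphar": 0, "chembl_assay": 0}

    def _add(compound: str, target: str, category: MoACategory, source: str, evidence: str):
        if allowed is not None and compound not in allowed:
            return
        counts[source] += 1
        slot = merged.setdefault((compound, target, category), {"sources": [], "evidence": []})
        if source not in slot["sources"]:
            slot["sources"].append(source)
        if evidence and evidence not in slot["evidence"]:
            slot["evidence"].append(evidence)

    for compound, target, term in mechanisms:
        _add(compound, target, map_chembl_action(term, chembl_mapping), "chembl_mechanism", term)
    for compound, target, term in drugbank:
        _add(compound, target, map_drugbank_action(term, drugbank_mapping), "drugbank", term)
    for compound, target, term in iuphar:
        _add(compound, target, map_iuphar_action(term, iuphar_mapping), "iuphar", term)
    for assay in assays:
        category = annotate_assay(assay, keyword_rules, active_cutoff)
        if category is EXCLUDED:
            continue
        _add(assay.compound_id, assay.target_id, category, "chembl_assay", assay.assay_description)

    records = [
        CompoundTargetRecord(
            compound_id=compound,
            target_id=target,
            category=category,
            source=";".join(slot["sources"]),
            evidence="; ".join(slot["evidence"]),
        )
        for (compound, target, category), slot in sorted(
            merged.items(), key=lambda kv: (kv[0][0], kv[0][1], int(kv[0][2]))
        )
    ]
    logger.info(
        "build_profile: %d harmonized triples (%s)",
        len(records),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    if allowed is not None and not records:
        logger.warning("build_profile: no records left after compound filtering")
    return records
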