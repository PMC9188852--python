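"""Cross-source consistency filtering of causal profiles.

Each unique (compound, target) pair may carry several mode-of-action
categories coming from different sources. Directional categories 1 and 2 are
sub-groups of the undirected "active" category 3, so {1,3} and {2,3} are
consistent and resolve to the more specific member. Category 1 together with
2 (opposite directions), or category 4 (inactive) together with any active
category, is a contradiction and the pair is removed entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .causal_profile import CompoundTargetRecord, MoACategory

logger = logging.getLogger("causalnet")


class _RemovedType:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "Removed"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`resolve_pair` for contradictory category sets.
REMOVED = _RemovedType()


@dataclass(frozen=True)
class ConsistencyReport:
    """Bookkeeping over unique (compound, target, category) connections."""

    n_input_unique: int
    n_removed: int
    n_retained: int

    def __post_init__(self):
        if self.n_removed + self.n_retained != self.n_input_unique:
            raise ValueError("removed + retained must equal input connections")

    @property
    def percent_consistent(self) -> float:
        if self.n_input_unique == 0:
            return 100.0
        return 100.0 * self.n_retained / self.n_input_unique


def resolve_pair(categories: set[MoACategory] | frozenset[MoACategory]) -> MoACategory | _RemovedType:
    """Resolve the category set of one (compound, target) pair.

    Singletons map to themselves; {1,3} -> 1 and {2,3} -> 2 (the directional
    sub-group is the more specific label); any set containing both directions
    (1 and 2), or inactive (4) together with any active category, is removed.
    """
    cats = {MoACategory(c) for c in categories}
    if not cats:
        raise ValueError("category set must be non-empty")
    if MoACategory.POSITIVE in cats and MoACategory.NEGATIVE in cats:
        return REMOVED
    if MoACategory.INACTIVE in cats and len(cats) > 1:
        return REMOVED
    if MoACategory.POSITIVE in cats:
        return MoACategory.POSITIVE
    if MoACategory.NEGATIVE in cats:
        return MoACategory.NEGATIVE
    return next(iter(cats))


def apply_consistency(
    records: list[CompoundTargetRecord],
) -> tuple[list[CompoundTargetRecord], ConsistencyReport]:
    """Remove contradictory pairs; keep one resolved record per surviving pair.

    Counts are over unique (compound, target, category) connections: every
    connection belonging to a contradictory pair counts as removed, and all
    connections of an agreeing pair count as retained.
    """
    by_pair: dict[tuple[str, str], list[CompoundTargetRecord]] = {}
    seen_triples: set[tuple[str, str, MoACategory]] = set()
    for record in records:
        triple = (record.compound_id, record.target_id, record.category)
        if triple in seen_triples:
            continue
        seen_triples.add(triple)
        by_pair.setdefault((record.compound_id, record.target_id), []).append(record)

    resolved_records: list[CompoundTargetRecord] = []
    n_removed = 0
    n_retained = 0
    for (compound, target), pair_records in sorted(by_pair.items()):
        categories = {r.category for r in pair_records}
        outcome = resolve_pair(categories)
        if outcome is REMOVED:
            n_removed += len(categories)
            continue
        n_retained += len(categories)
        sources: list[str] = []
        evidence: list[str] = []
        for r in pair_records:
            for s in r.source.split(";"):
                if s and s not in sources:
                    sources.append(s)
            if r.evidence and r.evidence not in evidence:
                evidence.append(r.evidence)
        resolved_records.append(
            CompoundTargetRecord(
                compound_id=compound,
                target_id=target,
                category=outcome,
                source=";".join(sources),
                evidence="; ".join(evidence),
            )
        )

    report = ConsistencyReport(
        n_input_unique=len(seen_triples), n_removed=n_removed, n_retained=n_retained
    )
    logger.info(
        "consistency: %d unique connections, %d removed, %d retained (%.1f%% consistent)",
        report.n_input_unique,
        report.n_removed,
        report.n_retained,
        report.percent_consistent,
    )
    return resolved_records, report
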