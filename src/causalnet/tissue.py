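"""Tissue-specific filtering of causal profiles.

A record survives iff its target protein is present in the expression table
and listed as expressed in the tissue of interest (case-insensitive name
match). Presence/absence only — no expression-level threshold. Proteins
missing from the table altogether are dropped but counted separately, since
proteome coverage gaps (not true absence) are a known caveat of
expression resources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .causal_profile import CompoundTargetRecord
from .io_formats import ExpressionRecord

logger = logging.getLogger("causalnet")


@dataclass(frozen=True)
class TissueFilterStats:
    n_retained: int
    n_dropped_not_in_tissue: int
    n_dropped_no_expression_data: int


def filter_tissue(
    records: list[CompoundTargetRecord],
    expression: list[ExpressionRecord],
    tissue: str,
) -> tuple[list[CompoundTargetRecord], TissueFilterStats]:
    """Restrict a profile to targets expressed in ``tissue``."""
    if not tissue:
        raise ValueError("tissue name must be non-empty")
    by_protein: dict[str, ExpressionRecord] = {e.protein_id: e for e in expression}
    retained: list[CompoundTargetRecord] = []
    dropped_absent = 0
    dropped_tissue = 0
    for record in records:
        entry = by_protein.get(record.target_id)
        if entry is None:
            dropped_absent += 1
        elif entry.expressed_in(tissue):
            retained.append(record)
        else:
            dropped_tissue += 1
    stats = TissueFilterStats(
        n_retained=len(retained),
        n_dropped_not_in_tissue=dropped_tissue,
        n_dropped_no_expression_data=dropped_absent,
    )
    logger.info(
        "tissue filter (%s): retained %d, dropped %d (other tissue) + %d (no expression data)",
        tissue,
        stats.n_retained,
        stats.n_dropped_not_in_tissue,
        stats.n_dropped_no_expression_data,
    )
    if not retained:
        logger.warning("tissue filter (%s): no records retained", tissue)
    return retained, stats
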