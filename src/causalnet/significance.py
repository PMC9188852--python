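"""Toxicity group-contrast scoring of target proteins.

For each protein and modulation direction (1 = upregulated, 2 = downregulated)
we count the distinct compounds of the toxic group and of the non-toxic group
connected to the protein with that direction. The significance score is the
quotient of the two counts:

    score = n_tox / n_nontox            (n_nontox > 0)
    score = n_tox                       (protein only touched by the toxic group)

A protein-direction is flagged significant when the toxic group's involvement
is at least ``ratio_cutoff`` times the non-toxic group's (default 5), or — for
toxic-only proteins — when at least ``only_tox_cutoff`` toxic compounds are
connected (default 5). Absolute compound counts are the default; an optional
switch divides counts by group size first (the toxic-only rule always checks
the raw toxic count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .causal_profile import CompoundTargetRecord, MoACategory

logger = logging.getLogger("causalnet")

DIRECTIONS = (MoACategory.POSITIVE, MoACategory.NEGATIVE)


@dataclass(frozen=True)
class ScoringConfig:
    ratio_cutoff: float = 5.0
    only_tox_cutoff: int = 5
    normalize_by_group_size: bool = False

    def __post_init__(self):
        if self.ratio_cutoff <= 0 or self.only_tox_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class SignificanceEntry:
    protein_id: str
    direction: MoACategory
    n_tox: int
    n_nontox: int
    score: float
    significant: bool

    def __post_init__(self):
        if self.n_tox < 0 or self.n_nontox < 0 or (self.n_tox == 0 and self.n_nontox == 0):
            raise ValueError("compound counts must be non-negative and not both zero")
        if self.direction not in DIRECTIONS:
            raise ValueError("direction must be category 1 or 2")


def significance_score(
    n_tox: int,
    n_nontox: int,
    config: ScoringConfig | None = None,
    group_size_tox: int | None = None,
    group_size_nontox: int | None = None,
) -> tuple[float, bool]:
    """Score one protein-direction from its per-group compound counts."""
    config = config or ScoringConfig()
    if n_tox < 0 or n_nontox < 0:
        raise ValueError("counts must be non-negative")
    if n_tox == 0 and n_nontox == 0:
        raise ValueError("at least one group must have a connected compound")
    a, b = float(n_tox), float(n_nontox)
    if config.normalize_by_group_size:
        if not group_size_tox or not group_size_nontox:
            raise ValueError("group sizes required when normalizing")
        a /= group_size_tox
        b /= group_size_nontox
    if n_nontox > 0:
        score = a / b
        return score, score >= config.ratio_cutoff
    # toxic-only proteins: the cutoff applies to the raw compound count
    return a, n_tox >= config.only_tox_cutoff


def score_profile(
    tox_records: list[CompoundTargetRecord],
    nontox_records: list[CompoundTargetRecord],
    config: ScoringConfig | None = None,
    group_size_tox: int | None = None,
    group_size_nontox: int | None = None,
) -> list[SignificanceEntry]:
    """Score every (protein, direction) seen in either group's resolved profile.

    Only directional categories 1 and 2 contribute; category 3 ("active, no
    further information") never enters a directional count. Each compound is
    counted once per protein-direction regardless of evidence multiplicity.
    Entries are sorted by descending score, then protein id, then direction.
    """
    config = config or ScoringConfig()

    def _counts(records: list[CompoundTargetRecord]) -> dict[tuple[str, MoACategory], set[str]]:
        out: dict[tuple[str, MoACategory], set[str]] = {}
        for r in records:
            if r.category in DIRECTIONS:
                out.setdefault((r.target_id, r.category), set()).add(r.compound_id)
        return out

    tox_counts = _counts(tox_records)
    nontox_counts = _counts(nontox_records)
    entries = []
    for key in sorted(set(tox_counts) | set(nontox_counts), key=lambda k: (k[0], int(k[1]))):
        protein, direction = key
        n_tox = len(tox_counts.get(key, ()))
        n_nontox = len(nontox_counts.get(key, ()))
        score, significant = significance_score(
            n_tox, n_nontox, config, group_size_tox, group_size_nontox
        )
        entries.append(
            SignificanceEntry(
                protein_id=protein,
                direction=direction,
                n_tox=n_tox,
                n_nontox=n_nontox,
                score=score,
                significant=significant,
            )
        )
    entries.sort(key=lambda e: (-e.score, e.protein_id, int(e.direction)))
    logger.info(
        "significance: %d protein-direction entries, %d significant",
        len(entries),
        sum(e.significant for e in entries),
    )
    return entries


def entries_to_frame(
    entries: list[SignificanceEntry], gene_names: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate entries (scores shown unrounded; presentation rounds to 1 dp)."""
    rows = [
        {
            "protein_id": e.protein_id,
            "gene_name": (gene_names or {}).get(e.protein_id, ""),
            "direction": int(e.direction),
            "n_tox": e.n_tox,
            "n_nontox": e.n_nontox,
            "score": e.score,
            "significant": e.significant,
        }
        for e in entries
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "gene_name", "direction", "n_tox", "n_nontox", "score", "significant"],
    )
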