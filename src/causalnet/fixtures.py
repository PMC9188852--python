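"""Synthetic input generator with planted, parameterized ground truth.

Emits every file dialect the pipeline reads — compound group lists, curated
mechanism / assay / interaction / DrugBank-skim tables, a protein->tissues
expression table, a weighted interaction edge list, a causal interaction TSV
and a GMT pathway collection — together with a machine-readable truth object,
so every stage and the end-to-end pipeline can be tested without downloads.

Planted structure:

* a set of significant proteins per direction, connected to ``separation``
  times more toxic-group than non-toxic-group compounds (or to >= 5 toxic
  compounds only), all expressed in the focal tissue;
* decoy proteins with balanced group connectivity (contrast ratio 1) or with
  sub-cutoff toxic-only counts, never reaching significance;
* a configurable fraction of extra compound-target pairs given contradictory
  categories, exercising the consistency filter;
* a high-confidence clique among the significant proteins plus random decoy
  edges; directed causal edges among significant proteins (one protein
  upregulating several partners); one pathway built from the seed
  neighborhood plus random decoy pathways.

Assay descriptions are built from templates around the packaged keyword
vocabulary, so text-mining precision and recall on fixtures are 1.0 by
construction. pChEMBL values are drawn category-consistently on either side
of the activity cutoff. All output is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .causal_profile import MoACategory

#: per-source category-consistent vocabulary used when emitting rows
_CHEMBL_TERMS = {1: ["AGONIST", "ACTIVATOR"], 2: ["ANTAGONIST", "INHIBITOR", "BLOCKER"], 3: ["MODULATOR"]}
_IUPHAR_TERMS = {1: ["Activation", "Full agonist"], 2: ["Inhibition", "Antagonist"], 3: ["Binding"]}
_DRUGBANK_TERMS = {1: ["agonist", "activator"], 2: ["inhibitor", "antagonist"], 3: ["modulator"]}
_ASSAY_TEMPLATES = {
    1: [
        "Activation of {t} in cell-based reporter assay",
        "Channel opening activity at {t} measured by patch clamp",
    ],
    2: [
        "Inhibitor potency against {t} in biochemical assay",
        "Channel blocking activity at {t}",
        "Compound inhibiting {t} enzymatic turnover",
    ],
    # no directional keyword: resolves to category 3 above the cutoff,
    # category 4 below it
    0: [
        "Binding affinity to {t} determined by SPR",
        "Radioligand displacement at {t}",
    ],
}
_OTHER_TISSUES = ["brain", "heart", "kidney", "lung"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic data set (defaults mirror the DILI case study:
    180 toxic vs 272 non-toxic compounds, 4 upregulated and 13 downregulated
    planted significant proteins, contrast ratio 5)."""

    seed: int = 0
    n_tox: int = 180
    n_nontox: int = 272
    n_targets: int = 120
    n_sig_up: int = 4
    n_sig_down: int = 13
    separation: float = 5.0
    contradiction_rate: float = 0.05
    tissue_fraction: float = 0.8
    tissue: str = "liver"
    n_pathways: int = 12
    pathway_size: int = 8
    n_decoy_edges: int = 200

    def __post_init__(self):
        if min(self.n_tox, self.n_nontox, self.n_targets, self.n_pathways, self.pathway_size) < 1:
            raise ValueError("counts must be positive")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if not (0 <= self.contradiction_rate <= 1 and 0 <= self.tissue_fraction <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_sig_up + self.n_sig_down > self.n_targets:
            raise ValueError("more planted significant proteins than targets")
        needed = int(np.ceil(self.separation)) + 2
        if self.n_tox < needed:
            raise ValueError(f"n_tox must be at least {needed} to plant the separation")


@dataclass
class FixtureTruth:
    """Ground truth of one generated fixture set."""

    planted_significant: list[tuple[str, int]]
    contradiction_pairs: list[tuple[str, str]]
    tissue_expressed: list[str]
    absent_from_expression: list[str]
    enriched_pathway: str
    causal_pairs: list[tuple[str, str]]
    expected_consistency: dict[str, int]
    tox_compounds: list[str] = field(default_factory=list)
    nontox_compounds: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FixtureTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        raw["planted_significant"] = [tuple(x) for x in raw["planted_significant"]]
        raw["contradiction_pairs"] = [tuple(x) for x in raw["contradiction_pairs"]]
        raw["causal_pairs"] = [tuple(x) for x in raw["causal_pairs"]]
        return cls(**raw)


def _expected_consistency(triples: set[tuple[str, str, int]]) -> dict[str, int]:
    """Unique-connection accounting under the sub-group category semantics."""
    by_pair: dict[tuple[str, str], set[int]] = {}
    for compound, target, category in triples:
        by_pair.setdefault((compound, target), set()).add(category)
    removed = retained = 0
    for cats in by_pair.values():
        contradictory = (1 in cats and 2 in cats) or (4 in cats and len(cats) > 1)
        if contradictory:
            removed += len(cats)
        else:
            retained += len(cats)
    return {"n_input_unique": len(triples), "n_removed": removed, "n_retained": retained}


def generate(spec: FixtureSpec, outdir: str | Path) -> FixtureTruth:
    """Write all fixture files into ``outdir`` and return the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    tox = [f"CHEMBL1{i:05d}" for i in range(spec.n_tox)]
    nontox = [f"CHEMBL2{i:05d}" for i in range(spec.n_nontox)]
    targets = [f"P{10000 + i}" for i in range(spec.n_targets)]
    sig_down = targets[: spec.n_sig_down]
    sig_up = targets[spec.n_sig_down : spec.n_sig_down + spec.n_sig_up]
    significant = sig_down + sig_up
    decoys = targets[spec.n_sig_down + spec.n_sig_up :]

    mechanisms: list[dict] = []
    iuphar: list[dict] = []
    drugbank: list[dict] = []
    assays: list[dict] = []
    triples: set[tuple[str, str, int]] = set()
    used_pairs: set[tuple[str, str]] = set()

    def _pick(options: list[str]) -> str:
        return options[int(rng.integers(len(options)))]

    def _emit(compound: str, target: str, category: int) -> None:
        triples.add((compound, target, category))
        used_pairs.add((compound, target))
        source = int(rng.integers(4))
        if source == 0 and category in _CHEMBL_TERMS:
            mechanisms.append(
                {"compound_id": compound, "target_id": target, "action_type": _pick(_CHEMBL_TERMS[category])}
            )
        elif source == 1 and category in _IUPHAR_TERMS:
            iuphar.append(
                {"compound_id": compound, "target_id": target, "actions": _pick(_IUPHAR_TERMS[category])}
            )
        elif source == 2 and category in _DRUGBANK_TERMS:
            drugbank.append(
                {"compound_id": compound, "target_id": target, "action": _pick(_DRUGBANK_TERMS[category])}
            )
        else:
            template_key = category if category in (1, 2) else 0
            active = category != 4
            pchembl = rng.uniform(5.1, 9.0) if active else rng.uniform(3.0, 4.9)
            assays.append(
                {
                    "compound_id": compound,
                    "target_id": target,
                    "assay_description": _pick(_ASSAY_TEMPLATES[template_key]).format(t=target),
                    "pchembl_value": f"{pchembl:.2f}",
                    "activity_comment": "",
                }
            )

    # --- planted significant proteins -------------------------------------
    planted: list[tuple[str, int]] = []
    for i, target in enumerate(significant):
        direction = 2 if target in sig_down else 1
        k_non = i % 2
        k_tox = int(np.ceil(spec.separation * max(k_non, 1))) + i % 3
        k_tox = max(k_tox, 5)
        for compound in rng.choice(tox, size=k_tox, replace=False):
            _emit(str(compound), target, direction)
        for compound in rng.choice(nontox, size=k_non, replace=False):
            _emit(str(compound), target, direction)
        planted.append((target, direction))

    # --- decoys: balanced contrast, sub-cutoff toxic-only, undirected -----
    for j, target in enumerate(decoys):
        direction = 1 if j % 2 == 0 else 2
        if j % 5 == 4:
            # toxic-only but below the only-toxic cutoff
            for compound in rng.choice(tox, size=int(rng.integers(1, 5)), replace=False):
                _emit(str(compound), target, direction)
        else:
            k = 1 + j % 3
            for compound in rng.choice(tox, size=k, replace=False):
                _emit(str(compound), target, direction)
            for compound in rng.choice(nontox, size=k, replace=False):
                _emit(str(compound), target, direction)
        if rng.random() < 0.3:  # undirected "active" evidence, never counted
            group = tox if rng.random() < 0.5 else nontox
            _emit(str(rng.choice(group)), target, 3)

    # --- inactive (category 4) records on fresh pairs ---------------------
    n_inactive = max(1, spec.n_targets // 4)
    attempts = 0
    while n_inactive > 0 and attempts < 10 * spec.n_targets:
        attempts += 1
        compound = str(rng.choice(tox if rng.random() < 0.5 else nontox))
        target = str(rng.choice(targets))
        if (compound, target) in used_pairs:
            continue
        _emit(compound, target, 4)
        n_inactive -= 1

    # --- contradictions on fresh decoy pairs ------------------------------
    n_pairs_planted = len({(c, t) for c, t, _ in triples})
    n_contra = int(round(spec.contradiction_rate * n_pairs_planted))
    contradiction_pairs: list[tuple[str, str]] = []
    attempts = 0
    while len(contradiction_pairs) < n_contra and attempts < 100 * max(n_contra, 1):
        attempts += 1
        compound = str(rng.choice(tox if rng.random() < 0.5 else nontox))
        target = str(rng.choice(decoys if decoys else targets))
        if (compound, target) in used_pairs:
            continue
        _emit(compound, target, 1)
        _emit(compound, target, 2)
        contradiction_pairs.append((compound, target))

    # --- expression table --------------------------------------------------
    expression_rows = []
    tissue_expressed: list[str] = []
    absent: list[str] = []
    for target in targets:
        if target in significant:
            in_tissue = True
        else:
            roll = rng.random()
            if roll > spec.tissue_fraction and rng.random() < 0.4:
                absent.append(target)  # coverage gap: protein not in the table
                continue
            in_tissue = roll <= spec.tissue_fraction
        others = sorted(rng.choice(_OTHER_TISSUES, size=2, replace=False))
        tissues = ([spec.tissue] if in_tissue else []) + list(others)
        if in_tissue:
            tissue_expressed.append(target)
        expression_rows.append({"protein_id": target, "tissues": ";".join(tissues)})

    # --- interaction edges: clique on significant proteins + decoy edges --
    edge_rows = []
    edge_seen: set[tuple[str, str]] = set()
    for i, a in enumerate(significant):
        for b in significant[i + 1 :]:
            edge_rows.append({"protein_a": a, "protein_b": b, "combined_score": 900 + (i % 100)})
            edge_seen.add((a, b))
    for _ in range(spec.n_decoy_edges):
        a, b = (str(x) for x in rng.choice(targets, size=2, replace=False))
        key = tuple(sorted((a, b)))
        if key in edge_seen:
            continue
        edge_seen.add(key)
        edge_rows.append({"protein_a": key[0], "protein_b": key[1], "combined_score": int(rng.integers(150, 851))})

    # --- causal interactions: one protein upregulating several partners ---
    signor_rows = []
    causal_pairs: list[tuple[str, str]] = []
    hub = sig_down[0] if sig_down else significant[0]
    partners = [p for p in significant if p != hub][: max(3, len(significant) // 3)]
    for partner in partners:
        signor_rows.append(
            {"type_a": "protein", "id_a": hub, "type_b": "protein", "id_b": partner,
             "effect": "up-regulates quantity by expression"}
        )
        causal_pairs.append((hub, partner))
    if len(significant) >= 3:
        signor_rows.append(
            {"type_a": "protein", "id_a": significant[1], "type_b": "protein",
             "id_b": significant[2], "effect": "down-regulates activity"}
        )
        causal_pairs.append((significant[1], significant[2]))
    # rows the overlay must drop: non-protein entity, endpoint outside panel
    signor_rows.append(
        {"type_a": "chemical", "id_a": "CHEMBL999999", "type_b": "protein",
         "id_b": hub, "effect": "up-regulates"}
    )
    signor_rows.append(
        {"type_a": "protein", "id_a": "Q99999", "type_b": "protein",
         "id_b": hub, "effect": "down-regulates"}
    )

    # --- pathways: seed neighborhood + random decoy pathways --------------
    pathway_lines = []
    enriched_id = "PW0000"
    pathway_lines.append(
        "\t".join([enriched_id, "planted seed neighborhood"] + significant)
    )
    decoy_pool = decoys if len(decoys) >= spec.pathway_size else targets
    for p in range(1, spec.n_pathways):
        members = sorted(str(x) for x in rng.choice(decoy_pool, size=spec.pathway_size, replace=False))
        pathway_lines.append("\t".join([f"PW{p:04d}", f"decoy pathway {p}"] + members))

    # --- write everything ---------------------------------------------------
    (outdir / "tox_compounds.txt").write_text("\n".join(tox) + "\n", encoding="utf-8")
    (outdir / "nontox_compounds.txt").write_text("\n".join(nontox) + "\n", encoding="utf-8")
    pd.DataFrame(mechanisms, columns=["compound_id", "target_id", "action_type"]).to_csv(
        outdir / "mechanisms.tsv", sep="\t", index=False
    )
    pd.DataFrame(iuphar, columns=["compound_id", "target_id", "actions"]).to_csv(
        outdir / "iuphar.tsv", sep="\t", index=False
    )
    pd.DataFrame(drugbank, columns=["compound_id", "target_id", "action"]).to_csv(
        outdir / "drugbank.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        assays,
        columns=["compound_id", "target_id", "assay_description", "pchembl_value", "activity_comment"],
    ).to_csv(outdir / "assays.tsv", sep="\t", index=False)
    pd.DataFrame(expression_rows, columns=["protein_id", "tissues"]).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    pd.DataFrame(edge_rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        outdir / "string_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(signor_rows, columns=["type_a", "id_a", "type_b", "id_b", "effect"]).to_csv(
        outdir / "signor.tsv", sep="\t", index=False
    )
    (outdir / "pathways.gmt").write_text("\n".join(pathway_lines) + "\n", encoding="utf-8")

    truth = FixtureTruth(
        planted_significant=planted,
        contradiction_pairs=contradiction_pairs,
        tissue_expressed=tissue_expressed,
        absent_from_expression=absent,
        enriched_pathway=enriched_id,
        causal_pairs=causal_pairs,
        expected_consistency=_expected_consistency(triples),
        tox_compounds=tox,
        nontox_compounds=nontox,
    )
    truth.save(outdir / "truth.json")
    return truth
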