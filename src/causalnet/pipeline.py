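"""End-to-end orchestration of the five analysis components.

profile -> consistency -> tissue filter -> group-contrast scoring ->
network + causal overlay -> topological enrichment. Each stage is an
ordinary library function and can be run individually; :func:`run_all`
chains them, writes every intermediate table, and emits a manifest with
row counts plus the resolved configuration for provenance. The pipeline
proper contains no randomness, so repeated runs on identical inputs are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats
from .causal_profile import build_profile
from .consistency import apply_consistency
from .enrichment import EnrichmentConfig, enrich
from .network_causal import build_network, overlay_causal, to_multigraph
from .significance import ScoringConfig, entries_to_frame, score_profile
from .tissue import filter_tissue

logger = logging.getLogger("causalnet")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class RunConfig:
    """Paths and parameters for one full run."""

    mechanisms: str
    assays: str
    iuphar: str
    drugbank: str
    tox_compounds: str
    nontox_compounds: str
    expression: str
    string_edges: str
    signor: str
    pathways: str
    outdir: str
    tissue: str = "liver"
    pchembl_cutoff: float = 5.0
    ratio_cutoff: float = 5.0
    only_tox_cutoff: int = 5
    normalize_by_group_size: bool = False
    min_score: int = 400
    focus_direction: int = 2  # build network/enrichment from the downregulated set
    restart_prob: float = 0.5
    xd_threshold: float = 1.0
    gene_names: str | None = None

    _INPUT_FIELDS = (
        "mechanisms",
        "assays",
        "iuphar",
        "drugbank",
        "tox_compounds",
        "nontox_compounds",
        "expression",
        "string_edges",
        "signor",
        "pathways",
    )

    def validate_paths(self) -> None:
        for name in self._INPUT_FIELDS:
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError(f"input path for {name!r} does not exist: {path}")
        if self.gene_names and not Path(self.gene_names).exists():
            raise PipelineError(f"input path for 'gene_names' does not exist: {self.gene_names}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_all(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to the outdir)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}

    def _record(stage: str, path: Path, rows: int) -> None:
        manifest["stages"].setdefault(stage, []).append({"path": path.name, "rows": rows})

    def _stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        stage = _stage("profile")
        tox_group = io_formats.read_group_list(config.tox_compounds, label="tox")
        nontox_group = io_formats.read_group_list(config.nontox_compounds, label="nontox")
        mechanisms = [
            (r.compound_id, r.target_id, r.action_type)
            for r in io_formats.read_chembl_mechanisms(config.mechanisms)
        ]
        iuphar = [
            (r.compound_id, r.target_id, r.actions)
            for r in io_formats.read_iuphar_interactions(config.iuphar)
        ]
        drugbank = [
            (r.compound_id, r.target_id, r.action)
            for r in io_formats.read_drugbank_skim(config.drugbank)
        ]
        assays = io_formats.read_chembl_assays(config.assays)
        profiles = {}
        for label, group in (("tox", tox_group), ("nontox", nontox_group)):
            profiles[label] = build_profile(
                mechanisms=mechanisms,
                drugbank=drugbank,
                iuphar=iuphar,
                assays=assays,
                compound_filter=group.compound_ids,
                active_cutoff=config.pchembl_cutoff,
            )
            path = outdir / f"profile_{label}.tsv"
            io_formats.write_profile_tsv(profiles[label], path)
            _record(stage, path, len(profiles[label]))

        stage = _stage("consistency")
        resolved, report = apply_consistency(profiles["tox"] + profiles["nontox"])
        path = outdir / "profile_consistent.tsv"
        io_formats.write_profile_tsv(resolved, path)
        _record(stage, path, len(resolved))
        report_path = outdir / "consistency_report.json"
        report_path.write_text(
            json.dumps(
                {
                    "n_input_unique": report.n_input_unique,
                    "n_removed": report.n_removed,
                    "n_retained": report.n_retained,
                    "percent_consistent": report.percent_consistent,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        _record(stage, report_path, 1)

        stage = _stage("tissue")
        expression = io_formats.read_expression_table(config.expression)
        filtered, _stats = filter_tissue(resolved, expression, config.tissue)
        path = outdir / "profile_tissue.tsv"
        io_formats.write_profile_tsv(filtered, path)
        _record(stage, path, len(filtered))

        stage = _stage("score")
        tox_set = set(tox_group.compound_ids)
        nontox_set = set(nontox_group.compound_ids)
        tox_records = [r for r in filtered if r.compound_id in tox_set]
        nontox_records = [r for r in filtered if r.compound_id in nontox_set]
        scoring = ScoringConfig(
            ratio_cutoff=config.ratio_cutoff,
            only_tox_cutoff=config.only_tox_cutoff,
            normalize_by_group_size=config.normalize_by_group_size,
        )
        entries = score_profile(
            tox_records,
            nontox_records,
            scoring,
            group_size_tox=len(tox_group),
            group_size_nontox=len(nontox_group),
        )
        gene_names = io_formats.read_id_mapping(config.gene_names) if config.gene_names else {}
        frame = entries_to_frame(entries, gene_names)
        path = outdir / "significance.tsv"
        io_formats.write_results_tsv(frame, path)
        _record(stage, path, len(frame))
        focus = sorted(
            {
                e.protein_id
                for e in entries
                if e.significant and int(e.direction) == config.focus_direction
            }
        )
        if not focus:
            raise PipelineError(
                f"no significant proteins in direction {config.focus_direction}"
            )

        stage = _stage("network")
        string_edges = io_formats.read_string_edges(config.string_edges)
        signor = io_formats.read_signor_tsv(config.signor)
        display = overlay_causal(build_network(focus, string_edges, config.min_score), signor)
        graph = to_multigraph(display, gene_names)
        path = outdir / "network.graphml"
        io_formats.write_network_graphml(graph, path)
        _record(stage, path, graph.number_of_edges())
        path = outdir / "network_edges.tsv"
        io_formats.write_edgelist_tsv(graph, path)
        _record(stage, path, graph.number_of_edges())

        stage = _stage("enrich")
        pathways = io_formats.read_gmt(config.pathways)
        universe = sorted({r.target_id for r in filtered} | set(focus))
        enrichment_network = build_network(universe, string_edges, config.min_score)
        results = enrich(
            enrichment_network,
            focus,
            pathways,
            EnrichmentConfig(restart_prob=config.restart_prob, xd_threshold=config.xd_threshold),
        )
        result_frame = pd.DataFrame(
            [
                {
                    "pathway_id": r.pathway_id,
                    "annotation": r.name,
                    "xd_score": r.xd_score,
                    "overlap": r.overlap,
                    "pathway_size_in_network": r.pathway_size_in_network,
                    "fisher_p": r.fisher_p,
                    "q_value": r.q_value,
                    "significant_xd": r.significant_xd,
                }
                for r in results
            ],
            columns=[
                "pathway_id",
                "annotation",
                "xd_score",
                "overlap",
                "pathway_size_in_network",
                "fisher_p",
                "q_value",
                "significant_xd",
            ],
        )
        path = outdir / "enrichment.tsv"
        io_formats.write_results_tsv(result_frame, path)
        _record(stage, path, len(result_frame))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True), encoding="utf-8"
    )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
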