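# File format reference

All tabular files are UTF-8 TSV or CSV; the delimiter is chosen by extension
(`.tsv` tab, `.csv` comma) and never sniffed. Every reader validates its
required columns and fails with the missing column's name. Extra columns are
ignored.

## Compound group list (`*.txt`)

One compound identifier per line; blank lines and lines starting with `#` are
skipped. Duplicates are dropped with a warning. The group label defaults to
the file stem.

## Curated mechanism table (`mechanisms.tsv`)

| column | content |
|---|---|
| `compound_id` | compound identifier (opaque string, ChEMBL-style) |
| `target_id` | UniProt-style protein accession |
| `action_type` | curated action term, e.g. `AGONIST`, `BLOCKER` |

## Assay bioactivity table (`assays.tsv`)

| column | content |
|---|---|
| `compound_id`, `target_id` | as above |
| `assay_description` | free text mined for directional keywords |
| `pchembl_value` | −log10 molar activity; blank when unmeasured |
| `activity_comment` | free text (`active`, `Not Active`, `inconclusive`, …); may be blank |

## Pharmacology interaction table (`iuphar.tsv`)

Columns `compound_id`, `target_id`, `actions` (e.g. `Activation`,
`Inhibition`).

## DrugBank-skim table (`drugbank.tsv`)

Columns `compound_id`, `target_id`, `action` (lower-case action terms, e.g.
`inhibitor`). This is a minimal reconstruction of a skimmed target table:
compound, target accession and action term.

## Expression table (`expression.tsv`)

Columns `protein_id` and `tissues` (semicolon-separated tissue names, stored
case-preserved and matched case-insensitively).

## Weighted interaction edge list (`string_edges.tsv`)

Columns `protein_a`, `protein_b`, `combined_score` (integer 0–1000).
Self-loops are dropped at read time with a warning.

## Causal interaction TSV (`signor.tsv`)

Columns `type_a`, `id_a`, `type_b`, `id_b`, `effect`. Rows of any entity type
are read; only `protein`/`protein` rows survive the network overlay.

## Pathway collections (`*.gmt`)

Standard GMT: `name<TAB>description<TAB>member1<TAB>member2…`, one pathway
per line; duplicate pathway names are an error, duplicate members collapse.

## Outputs

* **Profile TSV** — `compound_id`, `target_id`, `category` (1–4), `source`
  (`;`-joined provenance), `evidence`; rows sorted by compound, target,
  category.
* **Significance TSV** — `protein_id`, `gene_name`, `direction` (1/2),
  `n_tox`, `n_nontox`, `score`, `significant`; sorted by descending score.
* **Network** — GraphML with node attribute `gene_name` and edge attributes
  `layer` (`confidence`/`causal`), `weight`, `effect`, `moi`; plus a TSV
  edge-list mirror with deterministic row order.
* **Enrichment TSV** — `pathway_id`, `annotation`, `xd_score`, `overlap`,
  `pathway_size_in_network`, `fisher_p`, `q_value`, `significant_xd`;
  sorted by descending XD score.
* **Consistency report JSON** — `n_input_unique`, `n_removed`,
  `n_retained`, `percent_consistent`.
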