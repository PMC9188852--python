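# Methods

`causalnet` implements an offline, five-component analysis of causal
drug–target relations for contrasting a toxic with a non-toxic compound
group: (i) harmonized causal target profiles, (ii) tissue-specific
filtering, (iii) a confidence-weighted protein network, (iv) a directed
causal protein–protein overlay, and (v) topology-based pathway enrichment.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data does and does not show.

## Mode-of-action harmonization

Drug–protein relations from heterogeneous sources are coded on four levels:
1 active–positive modulator, 2 active–negative modulator, 3 active with no
directional information, 4 inactive. Categories 1 and 2 are sub-groups of 3.
Curated vocabularies (mechanism `action_type`, pharmacology `actions`,
DrugBank-style `action`) are mapped by exact match after trimming and
case-folding; an unknown term is an error, never silently category 3,
because an unnoticed vocabulary drift would bias every downstream count.
The packaged DrugBank table is a reconstruction by analogy with the
four-level semantics; users with a curated mapping can supply their own.

Assay-level evidence is mined from free-text descriptions with
case-insensitive substring keywords (`inhibitor`, `inhibiting`,
`inhibit 50%`, `channel blocking activity` → 2; `activation`,
`channel opening activity` → 1), combined with a pChEMBL activity cutoff
(default 5.0, i.e. 10 µM; configurable because a single cutoff across
protein families is a deliberate simplification). The decision order is:
missing pChEMBL → excluded; a comment contradicting the measured side of
the cutoff (`active` below it, `not active`/`inactive` above it) or any
`inconclusive` comment → excluded; below-cutoff → category 4; above-cutoff
with exactly one keyword direction → that category, with both directions →
excluded unless an exclusion phrase voids one match, with none → category 3.
Exclusion phrases handle substring traps (`inactivation` contains
`activation`); the packaged list carries that one reconstructed pair.
Keyword evaluation is set-based, so rule order can never change an outcome.

## Consistency filtering

Per unique (compound, target) pair the category set is resolved:
singletons stand; {1,3} → 1 and {2,3} → 2 (the directional label is the
more specific member of the sub-group relation, which is the natural
retained label when a sub-group pair is declared consistent); 1 with 2, or
4 with any active category, is a contradiction and the pair is removed —
removed, not adjudicated, because the sources are not ranked. Bookkeeping
is over unique (compound, target, category) connections: all connections of
a contradictory pair count as removed, all connections of an agreeing pair
as retained, so `removed + retained = input` holds identically and the
percent-consistent statistic reproduces the published-style arithmetic
(e.g. 8186 of 8637 connections ≈ 94.8 %, printed as 95 %).

## Tissue filter

Presence/absence only: a record survives iff its target is listed for the
tissue (case-insensitive name match). Proteins missing from the expression
table are dropped but counted separately from proteins listed for other
tissues, because a coverage gap is not evidence of absence — the separate
count is the user's cue to curate.

## Significance score

For each protein and direction d ∈ {1, 2}, let `n_tox` and `n_nontox` be
the distinct-compound counts per group. The score is `n_tox / n_nontox`
(or `n_tox` when `n_nontox = 0`), flagged significant at ratio ≥ 5, or — for
toxic-only proteins — at ≥ 5 toxic compounds. Category-3 records never
enter a directional count. Absolute counts are the default; the optional
group-size normalization divides both counts by their group sizes before
the quotient while the toxic-only rule still checks the raw count (a
normalized count has no natural "5 compounds" reading). The score is a
screening quotient, not a test statistic: no p-value is attached, by design.

## Network and causal overlay

The confidence layer is the induced subgraph of a weighted edge list
(scores 0–1000, stored as weights ∈ [0, 1]) on the submitted protein set,
default `min_score = 400` — the conventional medium-confidence threshold
for such edge lists; submitted proteins without edges stay as isolated
nodes. The causal layer keeps protein–protein rows whose endpoints are
both network nodes, maps the effect text to a mode-of-interaction category
(`up-regulates*` → 1, `down-regulates*` → 2, `form complex`/`unknown`/
`binding` → 3) and collapses duplicate (source, target, effect) rows. The
two layers are never merged: they are different kinds of evidence, and the
GraphML/TSV outputs tag every edge with its layer.

## Topological enrichment

Node relevance is computed by a random walk with restart:
`s ← (1 − r)·W·s + r·e`, with `W` the column-normalized weighted adjacency,
`e` uniform over the seeds, restart probability `r = 0.5` by default
(exposed; the walk is not very sensitive to r in the mid-range, and 0.5
balances local and global structure). Columns of degree-zero nodes restart
to `e`, keeping the iteration on the probability simplex; convergence is
declared at L1 change < 1e-10 (well below any score difference the
downstream ranking uses) within 1000 iterations, else an error reporting
the residual. The iteration's fixed point equals the dense solve
`s = r (I − (1−r) W)⁻¹ e`, which the test suite verifies exhaustively on
all graphs with ≤ 4 nodes and on seeded random graphs up to 8 nodes.

Pathway scores: node scores are rescaled to a network-wide mean of one; a
pathway's raw score is the mean rescaled score of its in-network members,
and its XD score is the raw score minus the mean raw score over all scored
pathways — a deviation construction, so XD scores sum to zero and a score
above the threshold (default 1) marks a pathway whose members sit markedly
closer to the seeds than the average pathway. This scoring is this
package's own reconstruction of topology-aware "XD-style" enrichment as
popularized by network-enrichment web services; numerical agreement with
any particular service is not claimed. The overlap test is the one-sided
hypergeometric tail on seed∩pathway within the network-node universe, with
Benjamini–Hochberg adjustment across the scored pathways of one run.
Pathways with no in-network member are skipped and reported.

In `run-all`, the displayed network is the induced subgraph on the
significant proteins of the focus direction (default 2, downregulated),
while the enrichment walk runs on the full tissue-filtered protein
universe — enrichment needs background nodes for the deviation score to be
meaningful.

## Synthetic data

The generator emits every input dialect with planted truth. Defaults mirror
the drug-induced liver injury study conditions: 180 toxic vs 272 non-toxic
compounds, 4 planted upregulated and 13 planted downregulated significant
proteins, contrast separation 5, liver as the focal tissue; panel size,
pathway shape, background edge density, contradiction rate (default 0.05)
and tissue coverage (default 0.8) are parameters. Planted significant
proteins receive ≥ 5 toxic-only connections or a ≥ 5:1 toxic:non-toxic
ratio; decoys receive balanced connections (ratio 1) or sub-cutoff
toxic-only counts. Assay descriptions are built from templates around the
packaged keyword vocabulary and pChEMBL values are drawn
category-consistently (uniform on [5.1, 9.0] above, [3.0, 4.9] below the
cutoff), so text-mining precision/recall on fixtures is 1.0 by
construction. Contradictions are planted on dedicated fresh pairs so they
never touch a planted significant protein. The network contains a
high-confidence clique on the significant proteins plus random background
edges; one pathway is the seed neighborhood, the rest are random decoy
sets drawn from non-significant proteins.

What passing on fixtures does **not** show: real assay text is far noisier
than the templates (the keyword list is small and English-only); real
databases disagree more subtly than planted 1-vs-2 contradictions; real
group sizes are imbalanced in ways the balanced decoys do not probe; and
real pathway collections overlap heavily, while decoys here are disjoint
from the seeds. Fixture results validate the machinery, not database
coverage.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on
scaled-down conditions (40/60 compounds, 50 targets, 10 pathways, 20
generator seeds) — small enough to iterate comfortably while preserving
every planted contrast. The pipeline proper contains no randomness;
repeated runs on identical inputs are bit-identical, and the generator is
fully deterministic given its seed.

## Known limitations

* Keyword mining is substring matching, not NLP; novel phrasings fall into
  category 3 or are missed.
* The consistency filter removes, never weighs — a single bad source row
  can delete a well-supported pair.
* The tissue filter cannot distinguish true absence from missing coverage
  (it only counts the two cases separately).
* The XD reconstruction is one reasonable propagation/normalization choice
  among several; rankings are comparable within a run, not across tools.
* Live database clients are out of scope; inputs are flat-file exports.
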