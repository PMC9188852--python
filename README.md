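# causalnet

Offline, scriptable analysis of **causal drug–target relations** for
toxicity profiling. Given heterogeneous database exports — curated
mechanism-of-action records, assay-level bioactivity with free-text
descriptions, pharmacology interaction tables, a protein-expression atlas,
a weighted protein–protein edge list, a causal interaction table, and
pathway gene sets — `causalnet` contrasts a **toxic** with a **non-toxic**
compound group to find the proteins they preferentially up- or
downregulate, builds a causal protein network around them, and ranks the
pathways topologically closest to them. The motivating use case is
drug-induced liver injury (DILI): which liver-expressed proteins do
DILI-positive drugs hit that DILI-negative drugs spare, and which
metabolic pathways sit around them?

## The method in brief

1. **Causal profile.** Every source's vocabulary is harmonized into four
   mode-of-action categories: 1 active–positive modulator, 2
   active–negative modulator, 3 active without direction, 4 inactive (1 and
   2 are sub-groups of 3). Assay text is mined with directional keywords
   combined with a pChEMBL cutoff (pChEMBL ≥ 5, i.e. ≤ 10 µM, is active);
   records whose activity comment contradicts the measured value are
   excluded.
2. **Consistency.** Per (compound, target) pair, {1,3} resolves to 1 and
   {2,3} to 2; a pair annotated both 1 and 2, or 4 together with any active
   category, is removed as contradictory.
3. **Tissue filter.** Keep targets expressed in the tissue of interest
   (presence/absence; proteins missing from the atlas are counted
   separately).
4. **Significance score.** Per protein and direction d ∈ {1, 2}:

       score = n_tox / n_nontox        (n_nontox > 0)
       score = n_tox                   (toxic-only)

   flagged significant at score ≥ 5 (or ≥ 5 toxic-only compounds).
5. **Network + causal overlay + enrichment.** Induced confidence-weighted
   subgraph on the significant proteins; directed causal edges
   (up-/down-regulates → mode of interaction 1/2) overlaid from
   protein–protein interaction rows; then a random walk with restart from
   the significant set scores every pathway by its **XD score** (deviation
   of the pathway's mean walk probability from the average pathway; > 1 is
   significant) plus a one-sided hypergeometric overlap test with
   Benjamini–Hochberg q-values.

See `docs/methods.md` for the full model description and
`docs/formats.md` for every file dialect.

## Worked example

Generate a synthetic data set with planted signal (40 toxic vs 60
non-toxic compounds, 50 proteins, 17 planted significant protein–direction
pairs), then run the whole pipeline:

```sh
causalnet make-fixtures --seed 7 --outdir demo/inputs \
    --n-tox 40 --n-nontox 60 --n-targets 50 --n-pathways 10
causalnet run-all --config demo/config.yaml
```

where `demo/config.yaml` points each input key (`mechanisms`, `assays`,
`iuphar`, `drugbank`, `tox_compounds`, `nontox_compounds`, `expression`,
`string_edges`, `signor`, `pathways`) at the generated files and sets
`outdir: demo/out` and `tissue: liver`. The run logs each stage:

```
INFO consistency: 274 unique connections, 24 removed, 250 retained (91.2% consistent)
INFO tissue filter (liver): retained 209, dropped 12 (other tissue) + 29 (no expression data)
INFO significance: 40 protein-direction entries, 17 significant
INFO causal overlay: 6 edges kept, 1 non-protein rows dropped, 1 outside network
INFO enrichment: 10 pathways scored, 1 above XD threshold
```

`demo/out/significance.tsv` starts with the strongest contrasts — e.g.
`P10002  direction 2  n_tox 7  n_nontox 0  score 7.0  significant True`
means seven toxic-group compounds and no non-toxic compound downregulate
P10002. `demo/out/enrichment.tsv` ranks the planted seed-neighborhood
pathway first:

```
pathway_id  xd_score  fisher_p   q_value
PW0000      1.92      1.98e-07   1.98e-06
PW0003     -0.19      1.0        1.0
```

an XD score of 1.92 (> 1) with q ≈ 2·10⁻⁶ marks PW0000 as both
topologically close to and strongly overlapping the significant set, while
decoy pathways sit below the pathway average (negative XD). The remaining
outputs are the per-group profiles, the consistency report JSON, the
tissue-filtered profile, the GraphML network with `confidence` and
`causal` edge layers, and a manifest of all artifacts.

Every stage is also a separate subcommand (`profile`, `consistency`,
`tissue-filter`, `score`, `network`, `enrich`) operating on the same file
formats, and every function is importable from the `causalnet` package.

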