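# protpipe

Reusable, tested implementations of three bespoke analysis stages common to
nuclear-interactome / cardiac proteomics studies:

1. **AP-MS interactome scoring** — filter affinity-purification
   candidates by spectral-count evidence and rank them by an
   abundance-normalized enrichment index.
2. **TMT differential abundance** — calibrate a fold-change threshold from
   replicate-ratio histograms and call differential proteins with a
   concordant two-replicate fold rule.
3. **Functional-network enrichment** — build a confidence-thresholded
   association network over the differential set, cluster it, and compute
   GO-style term over-representation.

A synthetic-data module generates all inputs (spectral counts, TMT
matrices, edge tables, annotations) with planted ground truth, so every
stage is verifiable end to end without external downloads. The intended
users are proteomics analysts who want these filtering rules as an
auditable, scriptable library rather than spreadsheet arithmetic.

## The statistics at the core

**AP-MS.** A prey protein *i* with bait spectral count SpC_i and length
L_i gets a normalized spectral abundance factor within the purification,

    NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j)

with the sum over all bait-detected proteins (before any filtering). A
candidate is retained when it has ≥ 2 unique peptides, ≥ 10 bait spectra,
and is either absent from the control purification or ≥ 4-fold enriched
over it (inclusive thresholds); nuclear/unknown-localized candidates are
then ranked by the enrichment index EI_i = NSAF_i / A_i, where A_i is the
protein's whole-cell abundance in ppm (PAX-style). High EI flags proteins
captured far above their cellular baseline; the top 50 are reported.

**TMT.** Within-group replicate log2 ratios are fitted with a Gaussian
(nonlinear least squares on a Freedman–Diaconis histogram). The fold
threshold spanning a coverage *c* of that null distribution is

    τ = 2^(z_{(1+c)/2} · σ_log2)

so σ_log2 = log2(1.3)/1.6449 at c = 0.90 gives the canonical τ = 1.3
("90% of replicate ratios vary less than ±30%"). A protein is called
up when mutant_i/control_i ≥ τ in **both** replicate pairs, down when both
ratios are ≤ 1/τ, else unchanged.

**Network/enrichment.** Edges with combined confidence score strictly
above 0.4 induce a network on the query set; communities come from
deterministic greedy modularity maximization; term over-representation is
the hypergeometric upper tail P(X ≥ k) with BH q-values and the
up-regulated fraction reported per term.

## Worked example

```sh
protpipe simulate --seed 7 --out demo
protpipe apms-score --counts demo/spectral_counts.tsv \
    --meta demo/protein_meta.tsv --out demo/ranked.tsv
protpipe tmt-diff --tmt demo/tmt.tsv --channels demo/channels.json \
    --threshold 1.3 --out demo/diff
```

prints

```
wrote synthetic bundle to demo
22 ranked candidates -> demo/ranked.tsv
500 evaluable, 49 up / 52 down at tau=1.3 -> demo/diff
```

`demo/ranked.tsv` begins

```
rank  accession  bait_spc  control_spc  fold     nsaf             enrichment_index
1     P0397      67        3            22.33    0.0157715861262  0.157241108682
2     P0281      35        5            7        0.0496285639687  0.107324978576
```

— 22 of the 500 simulated proteins survive the evidence cascade (the
bundle plants 20 true interactors at 8-fold bait enrichment; the ranking
recovers most of them, cf. `demo/truth.json`), ordered by enrichment
index. The TMT summary (`demo/diff/summary.json`) reports replicate
concordance R² ≈ 0.98 per group, a fitted ratio sigma of ≈ 0.235 log2
units (88.8% of replicate ratios within ±1.3-fold — the generator is
calibrated to 90%), and 101 differential calls against 100 planted.

Library use mirrors the CLI: see `protpipe.score_apms`,
`protpipe.call_differential`, `protpipe.build_network`,
`protpipe.go_overrepresentation`.

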