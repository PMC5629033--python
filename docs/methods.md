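# Methods

## AP-MS candidate scoring

The scoring model treats spectral counts as semi-quantitative abundance
evidence within one affinity purification. The filter cascade is a pure
conjunction — unique peptides ≥ `min_unique_peptides` (default 2), bait
spectra ≥ `min_spectra` (default 10), and control-enrichment
(`control_spc == 0` or `bait/control ≥ min_fold`, default 4, all
inclusive) — so the localization filter and the count filter commute and
raising any threshold can only shrink the retained set. "Uniquely
identified" is a distinct OR-branch: proteins absent from the control
never enter a fold division and no pseudocount is ever added.

NSAF is computed over **all** bait-detected proteins before filtering.
NSAF is a within-purification relative abundance; computing it after
filtering would let the filter change the values of retained proteins,
which is both unstable and wrong. The denominator choice makes NSAF
invariant to rescaling all lengths by a constant.

The enrichment index EI = NSAF / abundance_ppm deliberately divides by a
*whole-cell* abundance estimate: a low-abundance protein captured
efficiently is the interesting signal. For that reason the default policy
for a missing (or zero) whole-cell abundance is to impute the dataset's
minimum positive abundance and flag the candidate rather than drop it —
excluding missing-abundance proteins would silently remove exactly the
low-abundance partners the index is designed to surface. `exclude` is
available for conservative runs. Ranking sorts by descending EI with ties
broken by accession so the top-k boundary is reproducible.

Open choices resolved here: bait counts are treated as already aggregated
across runs/gel slices (the table schema carries one bait column), and
ranking happens after the localization filter (filter-then-rank).

## TMT threshold calibration and differential calling

The caller is a fold-threshold classifier, not a significance test; there
is deliberately no moderated t-statistic. Its null model is the
within-group replicate ratio distribution: log2(rep1/rep2) for the two
control channels (and separately the two mutant channels). These ratios
are fitted with a Gaussian A·exp(−(x−μ)²/2σ²) by nonlinear least squares
on a Freedman–Diaconis-binned histogram; degenerate inputs or
non-convergence fall back to (median, 1.4826·MAD) with a
`robust_fallback` flag. The fold window containing coverage c of the
fitted null is τ = 2^(z_{(1+c)/2}·σ); at c = 0.90 and σ = log2(1.3)/1.6449
this inverts exactly to τ = 1.30.

Channel normalization defaults to total-sum (each column scaled to the
mean original column total) — the standard baseline when the upstream
normalization method is unknown; `none` is provided for matrices already
normalized upstream. Normalization is idempotent and preserves
within-channel protein ratios, so calls are invariant to applying it
twice.

Calls use the indexed pairing mutant_i/control_i (a cross-pairing of all
four ratios exists behind `replicate_pairing="cross"`). Direction requires
the same-side threshold in *both* replicates, boundaries inclusive;
comparisons are evaluated as `mutant ≥ τ·control` / `control ≥ τ·mutant`
so that swapping group labels maps up↔down exactly, including at floating
point boundaries. Proteins with any zero abundance in a used channel are
reported as not evaluable and excluded from the counts — a zero reporter
intensity is missingness, not biology, and imputing it would manufacture
infinite ratios. An `averaged` mode (threshold on the geometric-mean ratio
only) exists behind a flag for sensitivity analyses; the per-replicate
conjunction is the default reading of "in both replicates".

## Network and over-representation

The network stage induces a subgraph of the query proteins over the edge
vocabulary, keeping edges with combined score strictly greater than
`min_score` (0.4, the conventional medium-confidence floor); query
proteins absent from the vocabulary are listed as unmapped rather than
silently dropped. Mean degree is reported both over all mapped nodes
(2|E|/|V|) and over connected nodes, since both conventions appear in the
literature.

Clustering is deterministic greedy modularity maximization (CNM) on the
unweighted thresholded graph with lexicographically sorted node insertion,
so identical graphs yield identical labelings across runs and platforms.
This stands in for interactive plug-in clusterers whose algorithms and
database versions are not reproducible; correctness is therefore assessed
by planted-partition recovery (adjusted Rand > 0.8 under strong community
structure), not by matching any particular historical clustering.
Communities below `min_cluster_size` (default 3) are reported unclustered.

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n) per flat term (no ontology-graph propagation — that
belongs upstream of the input contract), thresholded on raw p < 0.05 to
match common practice in network figure legends, with BH q-values attached
for reporting only. The background defaults to the quantified-protein
universe supplied by the caller, not the whole annotation vocabulary. The
per-term up-fraction is the share of annotated query proteins called up.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (config, seed); planted truth is
returned and serialisable (`truth.json`).

* **Spectral counts** are negative-binomial (gamma–Poisson) with mean
  `background_mean` (default 5) and dispersion 10 (variance m + m²/10) —
  overdispersed, as real spectral counts are, but without shared-peptide
  effects or contaminant structure. Planted interactors multiply the bait
  mean by `enrichment_factor` (default 8); a quarter of them have control
  mean 0 to exercise the uniquely-identified branch. Lengths are uniform
  on [100, 3000] aa, whole-cell abundance log-uniform on [0.1, 1000] ppm,
  background localization {nuclear 0.3, unknown 0.2, other 0.5}. Planted
  interactors are assigned nuclear (0.6) or unknown (0.4) localization:
  the simulated bait is a nuclear transcription factor, so its true
  partners are nuclear or unannotated — with background localization the
  localization filter would discard half the planted truth by
  construction.
* **TMT abundances** are 2^(base + effect + noise) with base log2
  abundance Normal(10, 2) and independent per-channel noise of sd
  σ_ratio/√2, so within-group replicate log2 ratios have sd σ_ratio. The
  default σ_ratio = log2(1.3)/1.6449 ≈ 0.2301 is the calibration the
  threshold stage assumes (≈90% of replicate ratios within ±1.3-fold) and
  also yields replicate R² ≈ 0.99 on the log scale. No ratio compression,
  isotopic impurity, or peptide-level aggregation is simulated; passing
  tests show the classifier behaves correctly under its own noise model,
  not that real TMT data meet that model.
* **Networks** are planted-partition graphs (within-community edge
  probability p_within, scores uniform [0.6, 1.0]; between, p_between and
  [0.41, 0.6]).
* **Annotations** annotate each background protein per term at a base
  rate (default 0.05); planted terms annotate the differential set at
  odds× that rate.

## Problem sizes and numerical choices

Simulation-backed checks use n = 3000 proteins for TMT (matching the
scale at which the noise calibration stabilises), 500 proteins / 20
planted interactors for AP-MS, 50-node planted-partition graphs, and 200
seeds for the null-calibration experiment — large enough that Monte-Carlo
error is well below the tolerances asserted, small enough that the full
suite runs in seconds. Float output is serialised at 12 significant
digits; NSAF sums are checked to 1e-12; hypergeometric tails to 1e-10
against exact combinatorial summation.

## Known limitations

* The concordant fold rule has no multiplicity control by design: with
  duplicate replicates and a 90%-coverage threshold its per-direction
  false-call rate is (0.05)² = 0.0025 per protein. On 3000 proteins with
  100 planted moderate effects (|log2FC| = 1) that arithmetic already
  implies ≈14–16 false calls against ≈99 true ones — a false-discovery
  proportion of ~0.12–0.14, which the recovery test reports honestly.
  Practitioners wanting FDR control should treat the calls as a candidate
  set, not inference.
* Replicate pairing, upstream normalization, and whether the study's
  ratios were formed on averages are not recoverable from typical methods
  text; the defaults above are the plainest reading, with alternatives
  behind config flags.
* Only two replicates per group are supported by the calling stage; the
  container type admits more but the rule is defined for duplicates.
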