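# Methods

`crossomics` implements a comparative multi-omics ("systeomics") analysis
of the kind used to contrast biopharmaceutical production cell lines
(e.g. CHO vs. SP2/0) across growth phases: label-free quantification of
proteomes and transcriptomes, detection integration across omics layers,
confidence-interval/fold-change flagging of differential genes, exact
gene-set enrichment/depletion testing, and consensus membrane/secretome
classification. This note records the models, the defaults, and the places
where the design was genuinely open.

## Quantification

**NSAF.** For protein *i* with spectral count SpC_i and length L_i (amino
acids), the spectral abundance factor is SAF_i = SpC_i / L_i and

&nbsp;&nbsp;NSAF_i = SAF_i / Σ_j SAF_j

per sample. The denominator runs over the proteins present in the input
table — the *identified* proteome — so NSAF is a relative abundance on the
observed proteome and each sample's NSAF column sums to exactly 1. A sample
with no nonzero count has no defined NSAF and is rejected with its name.
Protein-group length is the length supplied for the group's representative
accession; no pseudocount is applied inside NSAF (zeros propagate, and only
the ratio comparison downstream adds one).

**FPKM.** FPKM_i = fragments_i · 10⁹ / (total_mapped · L_i) with L_i in
nucleotides. The library size `total_mapped` is passed explicitly (the
column sum of a filtered table is generally not the library size).

**Size factors.** The median-of-ratios estimator: the per-gene reference is
the geometric mean across samples, computed in log space and restricted to
genes with positive counts in every sample (numerical stability; genes with
any zero carry no information about relative depth under this estimator).
A sample's factor is the median ratio of its counts to the reference. For a
two-sample table (X, cX) this yields (1/√c, √c).

## Detection integration and differential flagging

A gene counts as *identified* at the mRNA level when FPKM > 0 and at the
protein level when it has at least one spectral count; both thresholds are
configurable (`detect_from_abundance(..., threshold=)`). Overlap accounting
partitions two detection profiles into (only A, both, only B); profiles
carry a namespace tag and refuse comparison across namespaces. Identifier
mapping is many-to-one with an explicit `drop_unmapped`/`keep_unmapped`
policy and a reported unmapped count.

Differential flagging works on per-gene log2 ratios
log2((a+ε)/(b+ε)). The pseudocount ε defaults to half the smallest nonzero
abundance of the pair, a conventional choice for detection-limited data.
Ratios are standardized as z = (log2r − center)/spread. The default
estimator is robust — center = median, spread = 1.4826·MAD (the MAD scaled
to be consistent for the normal) — because abundance-ratio distributions
are heavy-tailed and a mean/sd band would be dragged by the very outliers
the band is meant to isolate; `estimator="mean_sd"` is available. A gene is
flagged `outside_90`/`outside_95` when |z| exceeds the two-sided normal
quantile of the respective level (the highest exceeded level is reported),
and `fc_selected` when max(r, 1/r) ≥ the fold threshold (default 1.8, the
conventional cutoff for calling downregulation in this analysis style).
A degenerate spread of zero leaves every gene inside. Because the bulk of
genes defines the band, the procedure assumes most genes are null; under
exchangeable null log-ratios the outside-95 fraction converges to 5%
(verified by simulation in the acceptance suite).

## Enrichment and depletion

Detection of n genes from a universe of N is modeled as sampling without
replacement; for a term with K genes in the universe of which k were
detected, both tails are inclusive of the observed count:

&nbsp;&nbsp;p_enrich = P(X ≥ k), p_deplete = P(X ≤ k), X ~ Hypergeom(N, K, n),

matching the `hygecdf`/`hygepdf` convention, with the identity
p_enrich + p_deplete = 1 + P(X = k). Tails are accumulated in log space via
log-gamma, so N ~ 20,000 universes are exact to ~1e−12 (checked against
exhaustive enumeration of draws for all N ≤ 12, and against an independent
library implementation for large tuples).

The default universe is the *annotation universe* — every gene annotated to
at least one term of the loaded collection. The choice of universe is a
genuinely open design point in detection-based over-representation testing,
so it is an explicit policy (`annotation_universe` / `detected_union` /
`explicit`), recorded in the run manifest. Bonferroni families are one
namespace × one direction (enrichment and depletion are separate analyses);
the adjusted p is min(1, m·p) with m the number of tested terms. Terms with
K = 0 in the universe are not tested and do not count toward m.

Cross-dataset comparison matches KEGG pathways across species by their
trailing map number (`cge00561` ≡ `mmu00561` ≡ map 00561); GO ids map to
themselves. Ranked reports order by p ascending, break ties by the larger
deviation |k − nK/N|, then by term id, so output order is deterministic.
Significance matrices hold −log10(p) with p floored at 1e−16 (heatmap
ceiling 16); the heatmap's TSV twin contains exactly the plotted values and
is the testable artifact.

## Localization consensus

Upstream predictors are consumed as one normalized evidence table
(`protein_id, tmhmm_tm_count, phobius_tm_count, phobius_sp, signalp_sp,
targetp_loc ∈ {S, M, other, NA}, wolfpsort_loc ∈ {plasma_membrane,
extracellular, other, NA}`); the package does not re-implement the
predictors. The consensus is a union: membrane fires on TMHMM ≥ 1 helix,
Phobius ≥ 1 helix, or WoLF PSORT `plasma_membrane`; secreted fires on
SignalP, TargetP `S`, Phobius signal peptide, or WoLF PSORT
`extracellular`. A protein can be both. The union (rather than majority)
rule maximizes sensitivity for cataloging candidate membrane/secreted
proteins; each call carries the list of firing predictors so stricter
policies can be applied downstream, and `min_votes` switches to a k-of-n
consensus directly. The TM-helix cutoff (default 1) and the WoLF PSORT
compartment mapping are configurable.

## Synthetic data: what it emulates and what it does not

The generator produces a stated world with known ground truth:

* **Universe** — `n_genes` (default 1,000) genes with uniform protein
  lengths (100–1,000 aa) and gene lengths (300–3,000 nt); `n_terms`
  (default 50) terms drawn uniformly within `term_size_range`
  (default 10–50 genes).
* **Detection** — each gene is detected independently per dataset with
  `baseline_detect_prob` (default 0.8, matching deep-coverage studies in
  which most annotated genes are observed); genes of a *planted* term use
  its override probability instead, creating genuinely depleted or enriched
  terms. If planted terms overlap, the lowest-indexed term's override wins;
  planting disjoint terms is the supported use.
* **Abundance** — per-gene base abundance is log-normal
  (`abundance_log_mean=1`, `abundance_log_sd=1` on the natural-log scale,
  i.e. about an order of magnitude of spread, typical of proteome
  abundance distributions); condition B multiplies by 2^(planted log2 FC),
  plus optional independent per-condition log-normal noise
  (`condition_log_sd`, default 0). Counts are Poisson with mean
  abundance × length × depth — the simplest generative model under which
  NSAF and FPKM are the natural length-corrected estimators. Depths default
  to `protein_depth=0.01` (tens of spectral counts per protein) and
  `rna_depth=0.05` (hundreds of fragments per gene).
* **Predictors** — true labels drawn with `frac_membrane`, `frac_secreted`
  (defaults 0.2/0.2) and an explicit `frac_both` (default: the independence
  product); each predictor errs independently with
  `predictor_error_rate` (default 0). WoLF PSORT, being
  single-compartment, picks one of the two compartments at random for
  both-labeled proteins.

One global seed expands into named `SeedSequence` substreams (universe,
detection, abundance, predictors), so reconfiguring a later stage never
perturbs earlier draws and a fixed seed gives byte-identical output files.

The generator does **not** emulate: peptide-level identification and FDR
filtering, protein grouping ambiguity, correlated detection within
complexes, length-biased detection probability, overdispersed counts, or
batch effects. A green planted-recovery test therefore establishes that the
statistics recover signal of the planted kind at the stated rates — not
that real LC-MS/MS or RNA-seq data meet these assumptions. One consequence
is worth noting explicitly: under Poisson counts the log-ratio variance
depends on expected depth per gene, so a pooled z-band on count-derived
ratios is not exactly 95%-calibrated gene-wise; the null-calibration
guarantee is stated (and tested) for exchangeable log-ratios, which the
count path approaches only at high depth.

## Pipeline and reproducibility

`run_pipeline` executes simulate → quantify → integrate → enrich →
localize → report; any stage subset can be selected, a failing stage halts
the run with its name and leaves a `FAILED` marker beside the partial
outputs. The manifest records the package version, the full configuration
echo (every default the analysis depends on: universe policy, estimator,
pseudocount, thresholds, p-floor), SHA-256 checksums of all inputs and
outputs, per-stage row counts, and timestamps. All data outputs are
byte-identical across runs of the same configuration and seed; the
timestamps (and the echoed output directory) are the only volatile manifest
fields.

## Known limitations

* The hypergeometric test conditions on n; with discrete counts the null
  fraction of terms below a raw 0.05 threshold is at most, and slightly
  below, 5%.
* NSAF comparisons across samples assume similar identified-proteome
  composition; strong compositional shifts bias relative abundances.
* The CI band is a descriptive outlier rule on one comparison, not a
  replicate-based significance test; with biological replicates a
  count-model test (e.g. negative-binomial) is preferable.
* Cross-species comparison by uppercased symbol or map number ignores
  paralogy; supply an explicit ortholog map where that matters.
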