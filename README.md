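# phenolic

Annotation and expression analytics for microbial polyphenol
transformations in genome-resolved microbiome datasets.

Peatland and permafrost carbon models have long leaned on a single enzyme
class — oxygen-requiring phenol oxidases — to explain why polyphenols
accumulate under waterlogged, anoxic conditions (the "enzyme latch").
Testing that idea properly requires tracking *many* polyphenol-active gene
families across metagenome-assembled genomes (MAGs), their expression in
metatranscriptomes, and the polyphenol-like chemistry of the surrounding
organic matter. `phenolic` packages that entire desk-side workflow:

* **Annotation database** (`phenolic.db`) — gene families with per-family
  two-tier bitscore thresholds (a high-confidence **A** score and an
  optional high-recall **B** score), a substrate ontology, and
  transformation pathways labelled by oxygen dependence and trophic level
  (polymer / monomer / phenolic–benzoic acid). Stored as three flat TSV
  tables plus model artifacts.
* **Annotation engine** (`phenolic.annotate`) — profile-HMM searches (via
  pyhmmer) and local-alignment similarity searches (BLOSUM62, bitscores via
  the Karlin–Altschul conversion), with inclusive A/B rank assignment:
  `bitscore ≥ A` → rank A, `B ≤ bitscore < A` → rank B, else dropped.
* **Threshold calibration** (`phenolic.curation`) — the seed/decoy
  workflow: recruit homologs (top-*k* per query), consume an externally
  built alignment and phylogeny, reroot on the decoy clade, extract the
  seed clade's non-seed tips as a hold-out-safe training set, then set
  `A = min(seed bitscores)` and `B = min(in-clade homolog bitscores)`
  subject to both exceeding the best decoy score.
* **Distillation** (`phenolic.distill`) — a genome *encodes* a pathway when
  it satisfies strictly more than 50% of its steps, and *expresses* it in a
  sample when it encodes it and at least one pathway-member gene survives
  the count filter with a positive count. Pathway × (habitat, depth)
  summaries are z-scores of replicate-averaged summed expression.
* **Normalization** (`phenolic.normalize`) — counts below 5 are zeroed,
  converted to reads-per-kilobase (RPK), and scaled by trimmed-mean-of-
  M-values (TMM) factors computed on the RPK matrix — the geTMM transform:
  `geTMM_ij = RPK_ij / (Σ_i RPK_ij · f_j) · 10⁶`. The TMM computation
  (reference by the 75th-percentile rule, 30%/5% double trim on M and A,
  precision weights) is implemented here and cross-checked against
  Bioconductor edgeR in the test suite.
* **Genus metrics & statistics** (`phenolic.metrics`) — *talent* = number
  of unique pathways a genus expresses in a habitat (≥ 15 → talented;
  the threshold is recoverable as the empirical upper-tail 0.05 quantile of
  the genus distribution), *dominance* = a genus's average per-depth share
  of a trophic level's expression in a habitat (≥ 10% → dominant); plus
  two-sided Wilcoxon rank-sum comparisons and Benjamini–Hochberg-adjusted
  Pearson correlations within declared comparison groups.
* **Van Krevelen classification** (`phenolic.vankrevelen`) — FT-ICR-MS
  molecular formulae placed at (O:C, H:C) and assigned to refined regions:
  lignin (0.3 < O:C < 0.48, 1.08 < H:C < 1.28), hydrolysable tannin
  (0.6 < O:C < 0.7, 0.58 < H:C < 0.89), condensed tannin
  (0.4 < O:C < 0.5, 0.74 < H:C < 0.88); all inequalities strict. Percent
  polyphenol = intensity share of the three classes summed.
* **Synthetic data** (`phenolic.synth`) — seeded generators with planted
  ground truth for every stage: score-separable protein families, family
  trees with known clade structure, genomes with exact completeness
  targets, negative-binomial count matrices with planted talented/dominant
  genera over a 3 habitats × 3 depths × 3 replicates layout, and formula
  tables sampled inside each Van Krevelen region.

## Worked example

The `all` subcommand chains the demo workflow (synthetic workspace →
normalization → distillation → metrics → formula classification):

```sh
phenolic all --seed 7 --outdir demo
```

prints (stderr):

```
INFO phenolic: demo workspace written to demo/workspace
INFO phenolic: 1 talented, 1 dominant genera
INFO phenolic: end-to-end demo complete under demo
```

`demo/metrics/genus_metrics.tsv` then contains one row per genus; the two
planted genera are the only flagged rows:

```
genus        talent_count  talented  dominance_share  dominant  talented_or_dominant
g_bg00       6             False     0.0514           False     False
...
g_dominant   7             False     0.4892           True      True
g_talented   18            True      0.0658           False     True
```

`g_talented` expresses 18 unique pathways in its planted habitat (≥ 15 →
talented) but holds only 6.6% of any trophic level's expression (< 10%, not
dominant); `g_dominant` expresses just 7 pathways but contributes 48.9% of
monomer-level expression in the fen (dominant). Background genera sit at 6
pathways and ~4–5% shares. `demo/vankrev/percent_polyphenol.csv` reports the
intensity-weighted chemistry of the synthetic peak list:

```
sample_id,percent_lignin,percent_HT,percent_CT,percent_polyphenol
s1,31.95,22.37,24.57,78.89
```

Other entry points: `build-db` (seed/decoy calibration), `annotate`,
`normalize`, `distill`, `metrics`, `latch-stats`, `vankrev`, `fixtures` —
see `phenolic --help`. Every run writes a `provenance.json` (config
snapshot, input checksums, version); reruns with the same seed are
byte-identical.

## Scope

The package starts from called protein sequences, count matrices and
assigned molecular formulae. Assembly, binning, read mapping/counting,
taxonomy, multiple-sequence alignment and tree inference are consumed
through standard formats (FASTA, TSV, Newick), never reimplemented. See
`docs/methods.md` for model details, parameter defaults and limitations.
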