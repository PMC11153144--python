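# Methods

This note records the models, rules and numerical choices behind
`phenolic`, what the synthetic data do and do not emulate, and the known
limitations.

## Two-tier annotation thresholds

Each gene family carries a bitscore threshold pair. The **A score** is a
precision threshold: during calibration it is set to the minimum bitscore
obtained by any biochemically characterized *seed* sequence when searched
against a model built **without** those seeds (the seeds are a genuine
hold-out). Because A is a minimum over seeds, rank assignment treats it
inclusively — the weakest seed itself must annotate at rank A. The **B
score** is a recall threshold: the minimum bitscore of the in-clade seed
homologs (the sequences the model was built from), accepted only when it is
strictly above the highest score of any decoy-class sequence and strictly
below A. When the homolog minimum fails the decoy ceiling the family ships
A-only. Families imported from sources publishing a single cutoff store it
as A with B absent.

The published description of B-score curation ("tree placement and score
distribution") is judgement-based rather than algorithmic; the rule above
is the most permissive deterministic threshold consistent with the two hard
constraints (above every decoy, below A), and the per-sequence score table
in every `CalibrationResult` lets a curator override it.

Decoys and decoy homologs are treated identically (one decoy class) both
for the score ceiling and for tree rooting; the distinction is retained in
the score table's class column.

Rank assignment collapses multiple hits of one gene to one family to the
maximum bitscore before thresholding. The per-gene best-hit summary prefers
rank A over B, then higher bitscore, then the lexicographically smaller
family id; the long-form table is always retained, so the tie-break loses
no information.

### Search engines

Profile searches run through HMMER (pyhmmer) on HMMER3 artifacts; profile
bitscores are reported as-is. Similarity searches use local pairwise
alignment with BLOSUM62 and affine gaps (open −11, extend −1 per additional
column), with raw scores converted to bits via the Karlin–Altschul
parameters for gapped BLOSUM62 (λ = 0.267, K = 0.041). A family's hit is
the best bitscore over its representative sequences. The default reporting
floor for similarity hits is 25 bits — comfortably above chance for
protein-length queries — and is irrelevant to final annotations, which are
decided by the family thresholds alone.

## Clade extraction

The training-set extraction reroots the family tree on the edge above the
smallest clade containing every decoy-class tip and none of the seeds
(bipartition search, so the input rooting is irrelevant), takes the MRCA of
the seeds, and returns its tips minus seeds and minus decoy-class tips. If
no seed-free decoy clade exists, or a decoy-class tip falls inside the seed
MRCA, the function raises rather than silently returning a contaminated
training set. A seed clade with no interleaved homologs yields an empty
training set with a warning — a legal but useless calibration input.

Alignment trimming uses a fixed maximum gap fraction per column (default
0.9) instead of an adaptive gap-trimming heuristic: the downstream contract
only needs a deterministic, documented trim.

## Pathway distillation

A pathway is an ordered list of steps; each step is a set of alternative
families. Completeness is the fraction of steps with at least one annotated
family, and a genome **encodes** the pathway only when completeness is
strictly greater than 0.5 — exactly half does not qualify. Expression in a
sample additionally requires at least one pathway-member gene of that
genome to carry a positive count after the global filter.

The global filter zeroes counts below 5 (per cell; a per-gene-row variant
is available). A count of exactly 5 survives the filter and therefore
qualifies a pathway as expressed. The two printed rules ("remove counts
<5" and "read counts >5") disagree only at exactly 5; keeping the filter as
the single point of truth resolves the boundary in favour of ≥5.

Pathway × group summaries sum normalized expression over pathway-member
genes per sample, average over the replicates of each (habitat, depth)
group, and z-score each pathway across groups (population sd). A pathway
flat across all groups gets z = 0 rather than NaN so heatmap-style outputs
stay finite.

## geTMM normalization

Counts → RPK (count / kb of gene) → TMM factors on the RPK matrix →
per-million scaling by (RPK library size × factor). The TMM computation
follows the canonical definition: reference sample = the one whose
75th-percentile count proportion is closest to the mean of those; for each
sample, M = log₂ ratio and A = mean log₂ abundance over genes positive in
both sample and reference (no pseudo-counts); two-sided trims of 30% on M
and 5% on A (rank-based, matching the reference implementation's
`floor(n·trim)+1` bounds); factor = 2 to the precision-weighted mean of the
surviving M-values, with weights the inverse asymptotic variance
(N−x)/(N·x) + (R−r)/(R·r); factors rescaled to geometric mean 1. Degenerate
samples (no shared positive genes, or a single one) get factor 1 with a
warning; |M|ₘₐₓ < 10⁻⁶ short-circuits to factor 1.

One subtlety is worth stating precisely: the precision weights depend on
library depth, so multiplying a *single* sample's counts by a constant
shifts its weighted factor slightly (relative drift around 10⁻³ — the same
behavior as edgeR, against which the test suite cross-checks via Rscript).
Proportion-preserving changes (scaling all samples, or scaling one of
several proportional columns) are exactly neutral. `weighted=False`
switches to the plain trimmed mean, which is exactly invariant to
per-sample scaling; the weighted canonical form is the default.

All tuning parameters (min count 5, trim 0.30/0.05, weighting) are exposed
in the API and CLI.

## Genus metrics

Talent counts the unique pathways a genus expresses per habitat, pooling
member genomes and all samples of the habitat (union across depths and
replicates); a genus is talented when any habitat count reaches the
threshold (default 15, inclusive). The threshold is recoverable from data
as the smallest observed value whose empirical upper-tail fraction is ≤
0.05; when no value qualifies the result is flagged unattainable.

Dominance computes, per (trophic level, habitat, depth) stratum, each
genus's share of summed normalized expression over all genes annotated to
that trophic level's pathway families, then averages shares over depths
within the habitat; a genus is dominant when any (trophic level, habitat)
average reaches 10% (inclusive, with a 10⁻¹² absolute guard so a share that
is exactly the threshold up to float rounding qualifies). Strata with zero
community-wide expression are undefined and excluded from the average with
a warning. Genes annotated to families appearing in pathways of several
trophic levels are credited to each; membership is not conditioned on the
owning genome encoding the pathway — at the intended scale (fully encoded
fixture genomes, near-complete real pathways) the distinction is
immaterial, and the statuses table lets stricter accounting be layered on.

The pooling order is a documented choice: share-per-depth then average
(matching "in a habitat (per depth)"), with the alternative (pool depths
first) expressible by pre-aggregating the input.

## Statistics

Saturated/unsaturated comparisons use the two-sided Wilcoxon–Mann–Whitney
rank-sum test: exact enumeration when both groups have ≤ 10 observations
and the pooled data are tie-free, the tie-corrected normal approximation
with continuity correction otherwise (the exact path is verified against
full permutation enumeration for all group sizes ≤ 7 in the tests). Pearson
correlations are adjusted with Benjamini–Hochberg *within declared
comparison groups only* — the grouping is a required analysis input and is
never inferred, because pooling across unrelated comparison sets changes
the ranks and hence the adjusted values. Zero-variance variables yield
undefined correlations, reported as NaN and excluded from adjustment.

## Van Krevelen classes

Classification uses only O:C and H:C; heteroatom counts pass through
untouched. All region boundaries are strict inequalities, so boundary
points class as `none`, and the three refined regions are pairwise disjoint
(verified by a region-overlap test and a 0.001-step grid sweep against a
literal transcription of the inequalities). Formulae matching no region are
labelled `none`, never forced to a nearest class. Percent polyphenol per
sample is the intensity-weighted percentage of lignin + HT + CT features;
replicate averaging is class-then-average (per-sample percentages averaged
within (habitat, depth) groups), the order exposed via the grouping
wrapper.

## Synthetic data

The generators are pure functions of (spec, seed) and exist to make every
rule exercisable offline with known answers:

* **Protein families** use a motif-plus-scaffold design: a family base
  sequence (150-residue scaffold, 40-residue functional motif) spawns seeds
  (5% substitution), seed homologs (15%), and decoys that keep the scaffold
  lineage at 50% divergence with the motif replaced — related but
  functionally distinct by construction. Generation searches every class
  against a homolog-built profile and a homolog representative set and
  *fails loudly* unless the weakest seed outscores the best decoy-class
  sequence by ≥ 20 bits on both engines; the realized margins are recorded
  in the truth table.
* **Clade trees** are random binary topologies with the seed clade
  guaranteed to have seeds on both sides of its root (so the seed MRCA is
  the whole clade), out-of-clade homologs grafted above it, and a decoy
  clade as sister.
* **Count matrices** follow the study layout of triplicate cores from
  three habitats (palsa, bog, fen) at three depths, with saturation
  assigned by the water-table rule (palsa unsaturated throughout, bog
  saturated below the surface, fen saturated throughout). Counts are
  negative-binomial (dispersion 10) over genes from one genome per genus.
  Background genera (24) encode six pathways each, spread across trophic
  levels by a stride-7 assignment, at mean 30 everywhere — far from both
  metric thresholds. The planted talented genus encodes/expresses 18
  pathways only in its habitat at mean 15 (talented, but ~6.5% share, not
  dominant); the planted dominant genus expresses the seven monomer
  pathways in the fen at mean 200 (~49% share, but 7 < 15 pathways, not
  talented). Gene lengths are drawn from 800–1200 bp — a realistic CDS
  band, narrow enough that RPK weighting cannot blur the planted margins.
* **Formula tables** rejection-sample integer compositions until the
  realized ratios fall strictly inside the requested region (or outside all
  regions for `none`).

What the fixtures do **not** emulate: real phylogenetic structure,
community compositional correlations, sequencing noise models beyond NB
overdispersion, alignment uncertainty, or homologs at the twilight zone of
detectability. Passing recovery tests therefore demonstrates that the
*rules* are implemented correctly and are recoverable at clearly separated
effect sizes — not that the thresholds are powerful on borderline real
data.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: 10
calibrated families, 50 randomized trees, 20 recovery seeds on a ~340-gene
× 27-sample matrix, 20 random 50×6 TMM matrices, and a 4-million-point
classification grid. These sizes were chosen to pin down the rules with
margins while keeping a full run in well under a minute per stage.

## Known limitations

* The similarity engine is a single-pair local aligner, not a heuristic
  database search; it is quadratic per pair and intended for curation-scale
  inputs, not for screening millions of reference sequences.
* Calibration assumes the externally supplied tree separates seeds from
  decoys; it flags but cannot repair a tree where they interleave.
* geTMM assumes most genes are not differentially expressed between any
  sample and the reference; grossly asymmetric matrices violate that
  assumption for any TMM-family method.
* The empirical threshold rule needs enough distinct observed values for a
  tail of ≤ α to exist; degenerate distributions are flagged.
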