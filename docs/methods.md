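# Methods

`trninfer` reconstructs a bacterial transcriptional regulatory network (TRN)
by combining three sources of evidence: conservation of upstream DNA motifs
across closely related genomes (phylogenetic footprinting), condition-specific
co-expression, and intrinsic properties of transcription factors (TFs). This
note records the models, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Pipeline overview

1. **Footprinting input.** For every gene the strand-aware upstream
   intergenic region (IGR) is extracted; only IGRs strictly longer than
   40 bp are kept (shorter gaps are typically operon-internal). Orthologous
   genes across the K related genomes contribute their IGRs to one
   footprinting group; groups need at least 4 IGR sequences and a member
   from the target genome.
2. **De novo motif discovery** on each group (ZOOPS model, both strands).
3. **Genome-wide scanning** of each discovered motif over the target-genome
   IGRs, retaining the best hit per IGR per strand at a word p-value
   threshold.
4. **Motif clustering**: motifs that identify the same genomic instances
   (hit-set overlap >= 33%, overlap coefficient on the smaller set) and are
   similar as matrices (pairwise comparison q < 0.01, Benjamini-Hochberg)
   are merged by single linkage.
5. **Expression refinement** of each motif cluster's hit genes into
   biclusters (gene subset + condition subset) with a permutation test.
6. **TF linking**: each (TF, bicluster) pair is scored on four criteria —
   expression correlation, genomic proximity, DNA-binding-domain (DBD)
   motif similarity, and phylogenetic co-occurrence — each converted to an
   empirical p-value against a 1000-draw permutation null, and combined as
   `R = -log10(p_corr * p_prox * p_dbd * p_pc)`. The rank-1 TF per cluster
   defines the comparative core network; targets are extended through
   predicted operons.
7. **Expression-only consensus** (CLR-style mutual information and a
   tree-ensemble importance scorer) combined as
   `R_exp = (1/3) * sum(-log10 p)` with a fixed divisor of 3, thresholded at
   a target precision on a gold standard (default 95%), and merged under
   TF-level precedence for the comparative core.

## Motif machinery

**Background model.** An order-3 Markov model with +1 pseudocount per
context cell, trained on all IGRs of all genomes. Window probabilities use
each position's conditional probability given its preceding context, so
window likelihoods are consistent across overlapping windows. Sequence
positions near a start fall back to the longest available context.

**ZOOPS discovery.** A zero-or-one-occurrence-per-sequence mixture model
fit by EM over all windows of both strands. Seeding matters more than
iteration count: half the seeds are windows containing the k-mers (k = 8)
that recur most often across the group — the signature of a shared site —
and half are random; seeds are batch-refined for 3 iterations and the two
best by log-likelihood ratio (LLR) are refined for 20 more. Widths 10 and
16 are searched by default (cap 30); discovered sites are masked before the
next of up to 3 motifs.

**Discovery significance.** The max-LLR statistic has no tractable closed
form, so the null is Monte Carlo: the same search applied to groups
resampled from the background model. Unit-scale calls estimate the null per
group (8 replicates, Student-t tail); the pipeline instead fits a
calibration curve once per run — null mean regressed on log total window
count per width, residual sd as spread — from ~75 background groups, which
is cheaper by the number of groups and equally calibrated in our checks.
A motif is reported when its tail probability is at most 0.01 (the
surrogate's E-value threshold).

**Scanning.** Scores are log2 odds against the order-0 stationary
background, rounded to a 1e-3 lattice; the p-value of a word score is exact,
by dynamic programming over the lattice (zero-frequency cells are floored at
1e-9 before taking logs). The default hit threshold is a word p-value of
1e-4. At that threshold a ~100k-window genome yields on the order of ten
chance best-hits per motif; these are deliberately tolerated because the
expression-refinement stage removes unrelated genes far more reliably than a
stricter scan threshold retains degenerate true sites (narrow motifs lose
mutated instances quickly as the threshold drops).

**Motif comparison.** Columns of the two frequency matrices are compared by
Pearson correlation; all ungapped alignments with >= 4 overlapping columns
in both orientations are scored by the SUM of column correlations (the mean
is reported as the similarity statistic). Using the sum rather than the
mean to pick the alignment is essential: sharp columns make the mean
saturate, so short chance overlaps of column-shuffled matrices would
otherwise dominate the null. The null is 1000 column shuffles of the second
matrix, maximised over the same alignments; observations beyond the shuffle
range get a Gumbel tail fitted to the null maxima by moments, because the
empirical floor 1/1001 is useless after multiple-testing control.
Pairwise p-values are computed only for motif pairs that already meet the
33% hit-overlap condition (the cluster rule needs both conditions, so other
pairs can never form edges) and BH-adjusted over that set.

**Hit identity for overlap** is (gene, window-midpoint bin) with 5 bp bins
matched up to +-1 bin, ignoring strand: variants of one motif discovered at
different widths or in opposite orientations must count as the same genomic
instance.

## Expression refinement

Rows are z-scored (ddof 1); constant rows are dropped. Co-expression is
always |Pearson r| since repression anti-correlates.

The bicluster search is a seed-and-grow procedure: seed with the
most-correlated gene pair (forced up to the minimum module size of 3),
then iterate (a) greedy condition removal — per step the leave-one-out
score of every condition is computed from sufficient statistics and up to 3
conditions whose individual removal improves the mean pairwise |corr| by
more than 0.005 are dropped, never below 30 conditions; (b) growth by genes
whose mean |corr| to the core exceeds max(0.5 * score, 0.15); (c) pruning of
genes below the same threshold. Three rounds suffice in practice. The
relative threshold makes the search robust when spurious scan hits outnumber
the true module, which is the realistic regime. A single motif cluster may
yield up to 3 modules (single-linkage clustering can chain distinct regulons
into one hit union; the refinement separates them).

**Significance.** The module score (mean pairwise |corr|) is compared with
1000 scores obtained by applying the same seed-and-grow search to random
gene sets drawn from a row-permuted copy of the matrix. Row permutation
destroys all genuine co-expression — a null drawn from the intact matrix
would rediscover real regulons and reject everything — while replaying the
search carries its selection bias into the null, without which the test
would be strongly anti-conservative. Null draws are matched to the observed
input-set and module sizes, bucketed conservatively (input size rounded up,
module size down) so distributions can be cached and shared; the loop stops
early once rejection (p > 0.001) is certain. Acceptance requires >= 3
genes, >= 30 conditions and p <= 0.001, mirroring standard biclustering
support/size/p-value constraints.

**Operons.** Distance-predicted operon pairs (adjacent, co-strand,
intergenic gap <= 50 bp — or an externally supplied pair list) extend
network targets transitively when the downstream gene also correlates with
its upstream partner at r >= 0.8 over all conditions (signed correlation;
operon co-transcription implies positive correlation).

## TF linking

* `corr`: mean |r| between the TF and each module gene over the module's
  condition subset (the per-gene condition subsets of the underlying idea
  are identified with the shared bicluster subset). Undefined if the TF is
  not on the array.
* `prox`: minimum distance in genes between the TF and any same-replicon
  module member, 0 for members; undefined if no member shares a replicon.
* `dbd`: every module motif is compared against a reference motif library;
  within the TF's DBD family the smallest BH-adjusted q over the library
  gives `-log10 q`; undefined if the family is absent.
* `pc`: for each genome a vector over ortholog groups of `-log10`(best hit
  p) is built; its correlation with the target genome's vector gives one
  scalar per genome, and the correlation of those scalars with the TF's
  presence/absence vector is the criterion. Undefined on zero variance
  (e.g. a TF present in every genome).

Each criterion's null pairs random TFs with random clusters (random
same-size gene sets for `corr`; a random family against a random cluster
motif for `dbd`), 1000 draws, seeded. Empirical p-values are floored at
1/1001 so the combined score stays finite; undefined criteria contribute
p = 1 (neutral evidence), which keeps the combination well defined without
rewarding missing data. Ties in the ranking break by (p_dbd, p_corr,
tf_id).

## Expression consensus

CLR: mutual information on 10 equal-frequency bins, background-corrected by
z-scoring each MI value against its TF row and its gene column, score
`sqrt(max(z_tf,0)^2 + max(z_gene,0)^2)`. Tree scorer: one randomized
extra-trees regression per target on the TF expression rows (50 trees,
sqrt feature subsampling), edge score = importance. Ranked lists truncate
at 50,000 edges. Null scores re-run the same scorer on a within-row
permuted matrix (10,000 draws); imported external lists instead sample the
empirical list scores with probability N/universe and 0 otherwise, since no
scorer is available to re-run. The combiner keeps the fixed divisor 3 even
when fewer approaches are supplied, so consensus scores remain comparable
across configurations; a third (e.g. ANOVA-based) ranking can be supplied
as an imported list. The precision-targeted cutoff walks ranked prefixes in
steps of 100 and returns the score at the largest prefix whose
gold-restricted precision meets the target (default 95%); without a gold
standard a fixed score cutoff of 1.3 applies.

## Network assembly and evaluation

Core edges run from each cluster's rank-1 TF to every member and
operon-extended gene; activation/repression signs from the signed TF-target
correlation are annotation only. The merge keeps every core edge and adds
consensus edges only for TFs absent from the core (TF-level precedence —
an expression edge for a core TF is dropped even if its target is new);
no re-thresholding happens after merging. Evaluation follows fixed
conventions: precision and recall on interaction sets, gold-restricted
precision when only some TFs have experimental data, PR curves at
100-prediction intervals, trapezoidal AUPR over recall anchored at recall 0
with the first point's precision, and per-TF report tables where no
prediction is NA, all-wrong is 0, and column averages run over non-NA
entries with half-up rounding to one decimal.

## Synthetic benchmark

The generator plants everything the pipeline is supposed to find: K genomes
(default 8) sharing 300 ortholog groups in a conserved order with local
shuffles and 10% ortholog loss; per-TF motifs (width 10-18, sharp columns
with occasional two-base degeneracy) embedded in regulon members' IGRs
(60-300 bp, order-3 Markov background) in genomes where the TF is present,
instance-sampled and point-mutated per genome; operon chains downstream of
some members with 20 bp gaps (hence no IGR of their own — they are only
reachable through operon extension); TF genes placed adjacent to a regulon
member half the time; 120 expression conditions in which each regulon
follows its TF's latent activity on a 40% active-condition subset (member
sign positive with probability 0.7), with operon members sharing their
head's profile; and a reference motif library holding each planted motif
re-estimated from 20 noisy sites under the TF's DBD family plus six decoy
families. All genes are laid on the forward strand so each gene's upstream
IGR is exactly its left gap (motif instances still land on either strand);
strand handling is exercised by the unit tests rather than the layout.
Presets: `easy` (mutation 0.02, noise sd 0.2, all TFs transcriptional),
`hard` (0.08 / 0.6 / one third post-transcriptional), and
`post_transcriptional` (easy conditions but every TF post-transcriptional,
scaled to 150 groups and 10 TFs).

What passing the benchmark shows: the stages compose, planted structure is
recovered at realistic divergence and noise, and the non-expression
criteria rescue regulators whose expression is uninformative. What it does
not show: performance on real compendia with correlated conditions, shared
motifs between paralogous TFs, horizontal transfer, variable-spacer
(sigma-factor-like) motifs, or RNA-level artifacts — none of which the
generator emulates.

## Problem sizes and determinism

The standard benchmark runs end-to-end in a few minutes on one core
(discovery dominates; all stages are NumPy-vectorised, and permutation
nulls are cached and shared across modules of similar size). Every
stochastic step takes an explicit seed; per-stage seeds are derived from
the run seed with stable tags, so whole runs are reproducible
bit-for-bit.

## Known limitations

* Gapped / variable-spacer motifs are out of model for both discovery and
  scanning.
* The scan p-value's exact distribution uses the order-0 background even
  though discovery uses order 3; this is the standard trade for an exact
  DP.
* Single-linkage motif clustering chains aggressively at permissive scan
  thresholds; the per-cluster module limit (3) bounds, but does not
  eliminate, the resulting loss of small regulons inside large chains.
* The empirical nulls (1000 draws) floor p-values at 1/1001, which caps a
  single criterion's contribution to the combined score at ~3.
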