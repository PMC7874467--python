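# Methods

`l1ripseq` re-implements, as a tested and reusable pipeline, a
locus-resolved analysis of ORF1p RIP-seq data: which individual LINE-1
genomic copies are transcribed, how intact their ORFs are, how strongly
LINE-1 and host RNA categories are enriched by the immunoprecipitation,
and whether the enriched host transcriptome resembles the p-body or the
stress-granule transcriptome. Because the questions are statistical, the
package ships a ground-truthed generator that emulates the experiment's
statistical structure, and every stage is validated against that truth.

## The synthetic experiment

The generator builds a single toy chromosome containing:

* **LINE-1-like loci.** One consensus element (default 2,700 bp) carries
  two engineered open reading frames - ORF1 (340 aa) and ORF2 (420 aa) -
  separated by a spacer, flanked by UTRs. Each locus is an independent
  copy of that consensus mutated at `divergence_rate` substitutions per
  site (default 0.02, roughly the within-young-subfamily divergence that
  makes short reads multi-map). Substitutions inside ORFs are re-drawn if
  they would create a stop codon, so the *engineered* nonsense mutations
  are the only stops in coding sequence and the intactness truth table is
  exact. Loci are assigned to three classes with configurable
  proportions: fully intact; ORF1 intact with a premature stop in ORF2;
  and ORF1 truncated by a premature stop placed in the middle 40% of the
  ORF (so neither fragment clears a 300 aa floor). Loci sit on the +
  strand by default; `minus_strand_fraction` enables reverse-strand
  copies, whose transcripts are the reverse complement of the genomic
  interval.
* **Host genes** in six categories: polyadenylated mRNA, histone-like
  non-polyA genes, mitochondrial-like genes, rRNA intervals, lncRNA-like
  genes, and circRNA host genes whose central 60% circularises through an
  annotated back-splice junction. Gene sequences are random, hence
  effectively unique.

**Expression truth.** Locus abundances within the LINE-1 compartment are
Dirichlet(0.8); the compartment as a whole is `l1_fraction_input`
(default 0.05%) of the input library, matching the observation that
LINE-1 is of order 0.1% of reads in this kind of experiment. Host gene
expression is log-normal (sigma 0.5) with per-category multipliers;
rRNA dominates both libraries (the library protocol does not deplete
it), histone-like genes are abundant, circRNA is rare. This composition
is not cosmetic: because rRNA is neither enriched nor depleted by the
pulldown, it anchors total-count normalization near the unenriched
scale, which is what makes "histone-like genes at about 1x while the
median gene is about 10x" a coherent statement (see Normalization).

**Pulldown truth.** Each transcript receives an IP enrichment factor
drawn log-normally per category: median 10x (log-sd 0.6) for
mRNA/lncRNA/MT-like, fixed exactly 1x for histone-like genes (they are
not polyadenylated, the hypothesised binding substrate), ~1x for rRNA,
median 34x for circRNA, and class-dependent factors for LINE-1 loci
(median 100x fully intact, 50x ORF1-intact, 5x ORF1-truncated,
mirroring the observation that enrichment tracks ORF intactness). IP
sampling weights are expression x enrichment, renormalised; input
weights are expression alone. For polyA gene categories the log
enrichment loads (loading 0.6) on a per-gene latent "granule" factor,
from which fabricated external p-body (loading 0.9) and stress-granule
(loading 0.8) tables are generated - so the granule comparison has a
known shared-structure answer, and conditioning on the p-body vector
should largely explain away the stress-granule correlation.

**Reads.** Paired-end fragments (length Normal(220, 30) truncated at the
75 bp read length) are placed uniformly on their transcript; mate 2 is
reverse-complemented; per-base errors are applied at
`sequencing_error_rate` (default 0.005). Circular transcripts are
sampled on their doubled sequence so fragments wrap the junction; a mate
whose interval crosses the junction is a back-splice junction read. A
count-level fast path (`simulate_count_tables`) draws per-feature
multinomial counts from the same weights - the exact marginal of the
read sampler - for statistics work at multi-million-read scale.

**Alignment emulation.** Loci differ from the consensus by substitutions
only, so the candidate placements of a LINE-1 fragment are exactly the
same-offset placements on every locus; the emulator scores each with
per-mate Hamming mismatch counts and reports all placements within a
mismatch budget (default 5 per mate). Host reads are tested against
their own gene; junction-spanning reads have no contiguous linear
placement and are reported unmapped. This is exact for data produced by
this generator and is not a general-purpose aligner: there are no
indels, clips, or spurious cross-category placements. Hits serialise to
multi-hit SAM (primary = fewest mismatches, ties to annotation order;
NM tags per mate) and round-trip losslessly into the quantifier.

## Intactness classification

Candidate ORFs are maximal ATG-to-stop frames on the sense strand
(LINE-1 ORFs are sense-encoded), strictly longer than 300 aa; a flag
admits stop-to-stop frames for heavily diverged elements. Each candidate
protein is locally aligned (BLOSUM62, affine gaps open 11 / extend 1 -
blastp-like conventions; configurable) to the ORF1p and ORF2p consensus
proteins. Coverage is the consensus span between the first and last
aligned consensus positions, internal gaps included, divided by
consensus length; an ORF is intact when some candidate covers >= 0.95.
Class assignment: ORF1-truncated iff ORF1 is not intact; otherwise fully
intact iff ORF2 is also intact. Raising the threshold can only demote a
locus (asserted as a property test). On the synthetic panel the
classifier is exact for divergence <= 0.03 because the truth construction
excludes accidental stops.

## EM quantification of multi-mapping reads

Fragments x loci weights are the per-base error likelihood
w_ij = eps^m (1-eps)^(L-m) with mismatches summed over both mates
(L = 2 x read length); mates multiply because they are conditionally
independent given the locus. Abundances theta maximise
sum_i log sum_j theta_j w_ij via EM from a uniform start; the likelihood
is concave in theta for fixed weights, so the start only affects ties,
which resolve to equal shares by symmetry. Convergence is on relative
log-likelihood change (1e-8, scale-free) with a 1,000-iteration cap and
an explicit `converged` flag. Reads hitting no locus carry no
information about theta and are dropped but counted. This is the core
multinomial-mixture treatment; generative refinements used by dedicated
LINE-1 quantifiers (passive/intronic transcription states, 5'
truncation models) are deliberately out of scope - the class-aggregation
and enrichment layers are agnostic to them. Per-class expression is the
sum of member-locus estimates.

Verification is two-route: on all small instances (<= 3 loci, <= 6
fragments) EM must match a dense simplex grid search (step 0.001 with a
local 2e-5 refinement) within 1e-3 per component; at scale (50 loci, 2%
divergence, 100k fragments) it must recover the generating abundances
with Spearman >= 0.9 and mean absolute error <= 0.005, with a monotone
log-likelihood trace.

## Enrichment estimation

**Normalization.** Three size-factor modes: median-of-ratios (each
sample's median ratio of counts to the featurewise geometric mean,
computed over features positive everywhere; the median is taken on the
ratio scale), total aligned reads, and exon-aligned reads (totals
restricted to exonic genes). The mode sets the *scale* of every fold
enrichment: median-of-ratios centres the typical feature at 1, which is
the wrong baseline when most of the genome is genuinely pulled down;
total-count normalization leaves the scale anchored by the dominant
unenriched rRNA compartment, so global enrichment remains visible. The
pipeline defaults to total-count; the exon mode mirrors gene-level
differential tools and shifts all enrichments by a constant factor.
Normalized counts are expressed per million of the geometric-mean
normalized library size, which makes every fold enrichment exactly
invariant to rescaling any single library's counts.

**Fold enrichment and testing.** E = (normalized IP mean + 0.5) /
(normalized input mean + 0.5); the pseudocount (configurable) tames
zero-input features. With one sample per group the p-value is a
two-sided two-proportion z-test of the feature's library share between
pooled IP and input counts; with replicates, a rank-sum across
per-replicate normalized values. BH step-up FDR is attached. Under a
simulated global null the fraction of features below FDR 5% stays below
5% plus Monte-Carlo error (checked over 200 simulated experiments).

**Category summaries** report median and quartiles of E and a two-sided
Mann-Whitney comparison against all other features (exact for both
groups <= 12 without ties, normal approximation with tie correction
otherwise). **Read-category fractions** assign each fragment
hierarchically in the fixed order rRNA -> exon -> LINE-1 -> other (first
match wins, reproducing a filter-then-count workflow); unmapped
fragments count as "other" and fractions sum to exactly 1. **circRNA**
is a single pooled feature: the sum of back-splice junction reads per
sample, since individual junctions are far too sparse to quantify.
**Expressed-locus overlap** between samples is Jaccard (|A&B|/|A|B|, as
a percent; the asymmetric alternative is not used and this choice is
documented because printed overlap conventions vary), with a locus
"expressed" when its expected count clears a floor of 1 per million
LINE-1 fragments (configurable; detection thresholds are rarely stated
in published analyses). Within-family vs between-family overlaps are
compared with a Welch one-sided t-test. A ddCT helper
(fold = 2^-ddCt) supports qPCR-style validation arithmetic.

## Granule comparison statistics

* **BH FDR**: step-up q_(i) = min_{j>=i} p_(j) n/j, capped at 1, input
  order preserved; validated against a brute-force implementation.
* **Overlap test**: 2x2 table of FDR-gated IP-enriched genes vs
  externally enriched genes within the universe of *jointly measured*
  genes (using all annotated genes would inflate the double-negative
  cell with genes never measurable in one assay; the choice is flagged in
  the output). Odds ratio ad/bc with a Haldane 0.5 correction, flagged,
  when any cell is zero. The p-value is the exact one-sided hypergeometric
  tail (enrichment direction; two-sided available), evaluated in log
  space so extreme significances are reported as log10 p rather than 0.
* **Spearman**: Pearson correlation of midranks (tie-aware); exact
  permutation p by full enumeration for n <= 8, t approximation with n-2
  df above. Full enumeration beyond n = 8 is computationally meaningless
  (n! blow-up) and the t approximation is already accurate there.
  Constant vectors yield NaN (undefined), never a silent 0.
* **Partial Spearman**: the first-order recursion
  rho_xy.z = (rho_xy - rho_xz rho_yz) / sqrt((1-rho_xz^2)(1-rho_yz^2))
  on tie-aware ranks, t approximation with n-3 df; cross-checked against
  the rank-regression residual method. Degenerate controls
  (|rho_xz| ~ 1) are reported as undefined.
* **join_and_compare** inner-joins on gene id, errors loudly when fewer
  than 10 genes join (disjoint id namespaces must not produce a silent
  empty result), and reports join and discard counts.

## Pipeline and reproducibility

`run_all` chains simulate -> classify-orfs -> quantify-l1 -> enrich ->
compare-granules, stopping at the first failing stage. All stage
randomness derives from the master seed through fixed offsets, so each
stage is independently reproducible; the manifest records a config hash,
per-file SHA-256 checksums and wall times, and a rerun with the same
config and seed is checksum-identical. The demo configuration (60 loci,
200k read pairs per library) runs in well under five minutes on one CPU.

## Problem sizes used in validation

The shipped validation uses 250 random small instances for the EM grid
oracle; 50 loci / 100k fragments for EM recovery; a 60-locus panel at 3%
divergence for the classifier; 1M reads per library for enrichment
recovery plus 200 replicates of 100k reads for the null calibration; an
exhaustive hypergeometric enumeration up to universe 60; and the demo
pipeline at 200k read pairs, run twice for determinism.

## What passing tests do and do not show

The generator emulates the *statistical* structure of the experiment:
multi-mapping from shared descent, ORF-breaking mutations, composition-
dominating rRNA, category-structured pulldown, junction-only circRNA
evidence, and a latent granule factor. It does not emulate real genomic
sequence, splicing, 5'-truncated LINE-1 copies, UMI/duplicate structure,
indel or clipped alignments, or realistic base-quality profiles.
Passing tests therefore demonstrate correctness of the estimators and
statistics under their modelling assumptions, not robustness to every
artefact of real libraries; in particular the alignment emulator's
exactness has no analogue in real aligner output, where mismapping adds
error the EM cannot see.

## Known limitations

* Host genes are counted by primary alignment rather than EM-resolved;
  only LINE-1 loci are EM-quantified (host genes are unique sequences
  here, so nothing is lost on synthetic data).
* The two-proportion test treats fragments as independent; overdispersion
  between biological replicates is only addressed via the rank-sum
  replicate mode.
* Exact Spearman permutation p-values stop at n = 8.
* The EM does not model passive (intronic/readthrough) LINE-1 signal; on
  real data that component inflates locus estimates and a dedicated
  generative quantifier should be preferred for final calls.
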