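# l1ripseq

Locus-resolved analysis of LINE-1 ORF1p RIP-seq experiments, exercised
end-to-end on ground-truthed synthetic data.

LINE-1 (L1) is the only autonomous human retrotransposon; full-length
copies encode ORF1p, an RNA-binding chaperone that coats the LINE-1
mRNA, and ORF2p, the endonuclease/reverse transcriptase. RNA
immunoprecipitation of ORF1p followed by sequencing (RIP-seq) asks three
questions that this package answers with tested, reusable code:

1. **Which genomic LINE-1 copies are transcribed?** Short reads from
   near-identical copies multi-map, so per-locus abundances
   θ are estimated by maximum likelihood over all reported alignments:
   each fragment i gets weight w\_ij = ε^m (1−ε)^(L−m) on locus j (m
   mismatches over L aligned bases), and EM iterates
   r\_ij = θ\_j w\_ij / Σ\_k θ\_k w\_ik,  θ\_j = Σ\_i r\_ij / n
   until the log-likelihood stabilises.
2. **How intact is each copy?** Candidate ORFs (> 300 aa, sense strand)
   are translated and locally aligned (BLOSUM62, affine gaps) to ORF1p /
   ORF2p consensus proteins; an ORF is intact when the alignment covers
   ≥ 95% of the consensus, giving three locus classes (fully intact /
   ORF1-intact–ORF2-truncated / ORF1-truncated) whose expression is the
   sum of member-locus estimates.
3. **What else does ORF1p pull down, and does it look like a granule
   transcriptome?** Per-feature fold enrichment E = normalized IP /
   normalized input (median-of-ratios, total-read or exon-read size
   factors), category summaries with rank-sum tests, pooled back-splice
   circRNA counting, BH-FDR gating, and comparison against external
   per-gene enrichment vectors (p-body, stress granule) via Spearman,
   partial Spearman and exact hypergeometric 2×2 overlap tests.

A first-class synthetic-data module generates a toy genome whose LINE-1
loci descend from a shared consensus (so reads genuinely multi-map),
carries engineered nonsense mutations matching each locus's class, and
draws paired input/IP libraries with known per-transcript pulldown
factors — so every estimator above is validated against known truth.
See `docs/methods.md` for the model details and design choices.

## Worked example

```bash
l1ripseq run-all --config configs/demo.yaml --out demo_out/
```

runs simulate → classify-orfs → quantify-l1 → enrich → compare-granules
on a 60-locus experiment with 200k read pairs per library (about a
minute on one CPU) and prints per-stage wall times. Inspecting the
outputs:

```python
>>> import json, pandas as pd
>>> calls = pd.read_csv("demo_out/intactness_calls.tsv", sep="\t")
>>> calls["intact_class"].value_counts()
intact_class
FULLY_INTACT              24
ORF1_TRUNC                18
ORF1_INTACT_ORF2_TRUNC    18
>>> theta = pd.read_csv("demo_out/l1_theta_ip.tsv", sep="\t")
>>> theta.nlargest(3, "theta")[["locus_id", "theta", "expected_count"]]
   locus_id     theta  expected_count
25   L1_025  0.069170      363.142481
42   L1_042  0.065527      344.018969
29   L1_029  0.060961      320.046439
>>> comp = json.load(open("demo_out/granule_comparison.json"))
>>> round(comp["pbody"]["spearman_rho"], 3), round(comp["pbody"]["odds_ratio"], 2)
(0.454, 9.0)
>>> round(comp["sg"]["spearman_rho"], 3), round(comp["sg"]["partial_rho"], 3)
(0.484, 0.254)
```

Reading: 24 of 60 simulated loci are fully intact and the classifier's
calls match the engineered truth; EM concentrates the IP library's
LINE-1 signal on a handful of highly expressed loci; gene enrichments
correlate with the fabricated p-body table (ρ ≈ 0.45, overlap odds
ratio 9 at FDR < 5%), and the apparent stress-granule correlation
(ρ ≈ 0.48) collapses to ρ ≈ 0.25 once the shared p-body structure is
controlled for by partial correlation — the behaviour the latent-factor
construction was designed to produce.

Every stage is also exposed as a library function
(`l1ripseq.simulate`, `.annotate`, `.em`, `.enrichment`, `.granules`,
`.pipeline`) and as individual CLI subcommands (`simulate`,
`classify-orfs`, `quantify-l1`, `enrich`, `compare-granules`) operating
on standard formats (FASTA/FASTQ/SAM/BED/GTF/TSV).

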