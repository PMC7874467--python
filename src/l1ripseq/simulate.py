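"""Ground-truthed synthetic RIP-seq data generator.

Builds a toy genome containing LINE-1-like loci derived from a single
shared consensus element (so reads genuinely multi-map between copies),
plus host genes in several categories (polyadenylated mRNA, histone-like
non-polyA genes, mitochondrial-like genes, rRNA intervals, lncRNA-like
genes, and circRNA host genes carrying a back-splice junction). Each
LINE-1 locus is assigned an ORF-intactness class and, where the class
requires it, an engineered premature stop codon; each transcript is
assigned a true expression level and a true IP pulldown enrichment
factor. Paired input/IP libraries are drawn from those truths, so every
downstream stage (classification, EM quantification, enrichment
estimation, granule comparison) can be checked against known answers.

The generator produces reads as code arrays plus an origin table; an
alignment *emulator* then reports every locus placement of each fragment
within a mismatch budget. Because loci differ from the consensus by
substitutions only (no indels), the candidate placements of a LINE-1
fragment are exactly the same-offset placements on every locus, which
the emulator exploits to stay vectorised; this is exact for sequences
produced by this generator, not a general-purpose aligner.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import BASES, STOP_CODONS, decode, encode, revcomp_codes

# Intactness class labels, shared with annotate/em modules.
FULLY_INTACT = "FULLY_INTACT"
ORF1_INTACT_ORF2_TRUNC = "ORF1_INTACT_ORF2_TRUNC"
ORF1_TRUNC = "ORF1_TRUNC"
CLASSES = (FULLY_INTACT, ORF1_INTACT_ORF2_TRUNC, ORF1_TRUNC)

HOST_CATEGORIES = ("mRNA", "histone", "MT", "rRNA", "lncRNA", "circRNA_host")

_CODON_TABLE = {}


def _codon_table() -> dict:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig cannot describe a valid experiment."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated RIP-seq experiment.

    Defaults describe the study conditions emulated throughout the test
    suite: ~60 LINE-1 copies at 2% divergence from a shared consensus,
    a few hundred host genes, and log-normal per-gene IP enrichments
    whose median sits in the 5-20x range while histone-like genes are
    pinned at 1x and circRNA is strongly enriched.
    """

    seed: int = 0
    # LINE-1 compartment
    n_l1_loci: int = 60
    l1_length: int = 2700
    divergence_rate: float = 0.02
    class_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    orf1_aa: int = 340
    orf2_aa: int = 420
    minus_strand_fraction: float = 0.0
    # host compartment
    host_categories: dict[str, int] = field(
        default_factory=lambda: {
            "mRNA": 120,
            "histone": 15,
            "MT": 13,
            "rRNA": 4,
            "lncRNA": 30,
            "circRNA_host": 10,
        }
    )
    gene_length: int = 1000
    # LINE-1 is ~0.1% of input reads; rRNA dominates both libraries (it is
    # not depleted by this protocol), which anchors total-count
    # normalization near the unenriched scale
    l1_fraction_input: float = 0.0005
    # sequencing
    read_length: int = 75
    fragment_mean: float = 220.0
    fragment_sd: float = 30.0
    n_reads_input: int = 50_000
    n_reads_ip: int = 50_000
    sequencing_error_rate: float = 0.005
    # pulldown model: per-category (log-space mean of the fold enrichment,
    # log-space sd). Histone-like genes are fixed at 1x (sd 0), rRNA is
    # neither enriched nor depleted, circRNA is strongly enriched.
    enrichment_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mRNA": (math.log(10.0), 0.6),
            "lncRNA": (math.log(10.0), 0.6),
            "histone": (0.0, 0.0),
            "MT": (math.log(10.0), 0.6),
            "rRNA": (0.0, 0.1),
            "circRNA_host": (math.log(10.0), 0.6),
            "circRNA": (math.log(34.0), 0.5),
            FULLY_INTACT: (math.log(100.0), 0.3),
            ORF1_INTACT_ORF2_TRUNC: (math.log(50.0), 0.3),
            ORF1_TRUNC: (math.log(5.0), 0.3),
        }
    )
    # relative mean expression multiplier per host category (rRNA dominates
    # real libraries because it is not depleted in this protocol)
    expression_multiplier: dict[str, float] = field(
        default_factory=lambda: {"rRNA": 6000.0, "MT": 2.0, "histone": 10.0, "circRNA": 0.25}
    )
    # granule latent-factor structure for fabricated external tables
    granule_loading: float = 0.6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        if not 0.0 <= self.divergence_rate <= 0.25:
            raise ConfigurationError("divergence_rate must be in [0, 0.25]")
        for name in ("n_l1_loci", "n_reads_input", "n_reads_ip", "gene_length"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(v < 0 for v in self.host_categories.values()):
            raise ConfigurationError("host category counts must be >= 0")
        orfs_nt = 3 * (self.orf1_aa + 1) + 3 * (self.orf2_aa + 1)
        if self.l1_length < orfs_nt + 90:
            raise ConfigurationError(
                f"l1_length={self.l1_length} too short to contain both ORFs "
                f"({orfs_nt} nt coding plus UTRs/spacer)"
            )
        if not 0 <= self.minus_strand_fraction <= 1:
            raise ConfigurationError("minus_strand_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    """A toy genome: one chromosome, LINE-1 loci and host genes.

    ``loci`` uses BED-style 0-based half-open genomic coordinates and also
    records ORF coordinates *within the element* (transcript coordinates,
    i.e. after strand adjustment). ``transcripts`` maps every feature id to
    its transcript sequence (code array); for minus-strand loci this is the
    reverse complement of the genomic interval.
    """

    chrom: str
    seq: np.ndarray  # uint8 codes for the whole chromosome
    loci: pd.DataFrame  # locus_id,start,end,strand,intact_class,orf coords
    genes: pd.DataFrame  # gene_id,category,start,end,circ_start,circ_end
    consensus_nt: str
    orf1_protein: str
    orf2_protein: str
    orf1_span: tuple[int, int]  # element coords, 0-based half-open, incl. stop
    orf2_span: tuple[int, int]
    transcripts: dict[str, np.ndarray]

    @property
    def seq_str(self) -> str:
        return decode(self.seq)

    def locus_matrix(self) -> np.ndarray:
        """Stack all locus transcript sequences into a (K, l1_length) array."""
        return np.stack([self.transcripts[i] for i in self.loci["locus_id"]])


def _random_coding(rng: np.random.Generator, n_aa: int) -> str:
    """A random open reading frame: ATG, n_aa-1 random non-stop codons, TAA."""
    codons = ["ATG"]
    bases = "ACGT"
    while len(codons) < n_aa:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


def _translate(nt: str) -> str:
    table = _codon_table()
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append(table.get(codon, "X"))
    return "".join(aa)


def _build_consensus(cfg: SimulationConfig, rng: np.random.Generator):
    """Consensus element: 5'UTR, ORF1, spacer, ORF2, 3'UTR."""
    orf1_nt = _random_coding(rng, cfg.orf1_aa)
    orf2_nt = _random_coding(rng, cfg.orf2_aa)
    utr5, spacer = 60, 30
    utr3 = cfg.l1_length - utr5 - spacer - len(orf1_nt) - len(orf2_nt)
    consensus = (
        _random_seq(rng, utr5)
        + orf1_nt
        + _random_seq(rng, spacer)
        + orf2_nt
        + _random_seq(rng, utr3)
    )
    orf1_span = (utr5, utr5 + len(orf1_nt))
    orf2_span = (utr5 + len(orf1_nt) + spacer, utr5 + len(orf1_nt) + spacer + len(orf2_nt))
    orf1_protein = _translate(orf1_nt)[:-1]  # drop the stop
    orf2_protein = _translate(consensus[orf2_span[0] : orf2_span[1]])[:-1]
    return consensus, orf1_span, orf2_span, orf1_protein, orf2_protein


def _mutate_locus(
    consensus: np.ndarray,
    orf_spans: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitute bases at `rate` per site without creating in-frame stop
    codons inside the given ORFs and without touching ORF start/stop codons.

    Keeping engineered stops the *only* stops in coding regions is what
    makes the intactness truth table exact, so substitutions that would
    introduce a stop are re-drawn among the remaining bases.
    """
    seq = consensus.copy()
    n = len(seq)
    protected = np.zeros(n, dtype=bool)
    for s, e in orf_spans:
        protected[s : s + 3] = True  # ATG
        protected[e - 3 : e] = True  # terminal stop
    sites = np.flatnonzero((rng.random(n) < rate) & ~protected)
    in_orf = np.zeros(n, dtype=np.int64) - 1
    for s, e in orf_spans:
        in_orf[s:e] = s
    for pos in sites:
        alternatives = [b for b in range(4) if b != seq[pos]]
        rng.shuffle(alternatives)
        orf_start = in_orf[pos]
        for alt in alternatives:
            old = seq[pos]
            seq[pos] = alt
            if orf_start < 0:
                break
            cpos = orf_start + 3 * ((pos - orf_start) // 3)
            codon = decode(seq[cpos : cpos + 3])
            if codon not in STOP_CODONS:
                break
            seq[pos] = old
    return seq


def _engineer_stop(
    seq: np.ndarray, orf_span: tuple[int, int], rng: np.random.Generator
) -> int:
    """Insert one premature TAA at a codon in the middle 40% of the ORF.

    Returns the codon index used. The middle placement guarantees neither
    the prefix nor the suffix of the broken ORF survives a 300 aa floor
    for the default ORF sizes.
    """
    s, e = orf_span
    n_codons = (e - s) // 3
    codon = int(rng.integers(int(0.3 * n_codons), int(0.7 * n_codons)))
    seq[s + 3 * codon : s + 3 * codon + 3] = encode("TAA")
    return codon


def _class_counts(n: int, proportions: tuple[float, float, float]) -> list[int]:
    counts = [int(math.floor(p * n)) for p in proportions]
    # distribute the remainder by largest fractional part, ties to earlier class
    rema = [p * n - c for p, c in zip(proportions, counts)]
    for i in sorted(range(3), key=lambda i: -rema[i])[: n - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the toy genome, LINE-1 locus annotation and gene annotation.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    consensus, orf1_span, orf2_span, orf1_p, orf2_p = _build_consensus(config, rng)
    consensus_codes = encode(consensus)
    orf_spans = [orf1_span, orf2_span]

    counts = _class_counts(config.n_l1_loci, config.class_proportions)
    classes = (
        [FULLY_INTACT] * counts[0]
        + [ORF1_INTACT_ORF2_TRUNC] * counts[1]
        + [ORF1_TRUNC] * counts[2]
    )
    rng.shuffle(classes)

    spacer = 100
    chrom_parts: list[np.ndarray] = [encode(_random_seq(rng, spacer))]
    pos = spacer
    loci_rows = []
    transcripts: dict[str, np.ndarray] = {}
    for j, cls in enumerate(classes):
        element = _mutate_locus(consensus_codes, orf_spans, config.divergence_rate, rng)
        if cls == ORF1_TRUNC:
            _engineer_stop(element, orf1_span, rng)
        elif cls == ORF1_INTACT_ORF2_TRUNC:
            _engineer_stop(element, orf2_span, rng)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        locus_id = f"L1_{j:03d}"
        genomic = revcomp_codes(element) if strand == "-" else element
        chrom_parts.append(genomic)
        chrom_parts.append(encode(_random_seq(rng, spacer)))
        loci_rows.append(
            {
                "locus_id": locus_id,
                "start": pos,
                "end": pos + len(element),
                "strand": strand,
                "intact_class": cls,
            }
        )
        transcripts[locus_id] = element
        pos += len(element) + spacer

    gene_rows = []
    gidx = 0
    for category in HOST_CATEGORIES:
        for _ in range(config.host_categories.get(category, 0)):
            gene_id = f"{category}_{gidx:04d}"
            gidx += 1
            gseq = encode(_random_seq(rng, config.gene_length))
            chrom_parts.append(gseq)
            chrom_parts.append(encode(_random_seq(rng, spacer)))
            row = {
                "gene_id": gene_id,
                "category": category,
                "start": pos,
                "end": pos + config.gene_length,
                "strand": "+",
                "circ_start": -1,
                "circ_end": -1,
            }
            if category == "circRNA_host":
                # back-splice junction: the central 60% of the gene circularises
                c0 = pos + int(0.2 * config.gene_length)
                c1 = pos + int(0.8 * config.gene_length)
                row["circ_start"], row["circ_end"] = c0, c1
                transcripts[f"circ|{gene_id}"] = gseq[c0 - pos : c1 - pos]
            gene_rows.append(row)
            transcripts[gene_id] = gseq
            pos += config.gene_length + spacer

    return SimulatedGenome(
        chrom="chrS",
        seq=np.concatenate(chrom_parts),
        loci=pd.DataFrame(loci_rows),
        genes=pd.DataFrame(gene_rows),
        consensus_nt=consensus,
        orf1_protein=orf1_p,
        orf2_protein=orf2_p,
        orf1_span=orf1_span,
        orf2_span=orf2_span,
        transcripts=transcripts,
    )


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth for one simulated experiment.

    ``features`` has one row per transcript (LINE-1 locus, gene, or circRNA)
    with its input expression fraction, true IP enrichment factor, and -
    for genes - the latent granule factor used to fabricate external
    p-body/stress-granule tables. ``theta_l1`` are the per-locus relative
    abundances within the LINE-1 compartment (they sum to 1).
    """

    features: pd.DataFrame
    theta_l1: pd.Series  # indexed by locus_id

    @property
    def input_probs(self) -> np.ndarray:
        return self.features["p_input"].to_numpy()

    @property
    def ip_probs(self) -> np.ndarray:
        return self.features["p_ip"].to_numpy()


def simulate_truth(genome: SimulatedGenome, config: SimulationConfig) -> TruthTable:
    """Draw true expression levels and IP enrichment factors."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []

    k = len(genome.loci)
    theta = rng.dirichlet(np.full(k, 0.8)) if k else np.array([])
    for (_, locus), th in zip(genome.loci.iterrows(), theta):
        mu, sd = config.enrichment_model[locus["intact_class"]]
        rows.append(
            {
                "feature_id": locus["locus_id"],
                "kind": "L1",
                "category": locus["intact_class"],
                "expression": th * config.l1_fraction_input,
                "enrichment": float(np.exp(rng.normal(mu, sd))),
                "latent": np.nan,
            }
        )

    n_genes = len(genome.genes)
    latent = rng.normal(size=n_genes)  # shared granule factor, one per gene
    a = config.granule_loading
    host_rows = []
    for (_, gene), g in zip(genome.genes.iterrows(), latent):
        cat = gene["category"]
        mult = config.expression_multiplier.get(cat, 1.0)
        mu, sd = config.enrichment_model[cat]
        # polyA categories load on the granule latent factor; the rest do not
        loads = cat in ("mRNA", "lncRNA", "circRNA_host")
        z = a * g + math.sqrt(1 - a * a) * rng.normal() if loads else rng.normal()
        host_rows.append(
            {
                "feature_id": gene["gene_id"],
                "kind": "gene",
                "category": cat,
                "expression": mult * float(rng.lognormal(0.0, 0.5)),
                "enrichment": float(np.exp(mu + sd * z)),
                "latent": g if loads else np.nan,
            }
        )
        if cat == "circRNA_host":
            cmu, csd = config.enrichment_model["circRNA"]
            cmult = config.expression_multiplier.get("circRNA", 1.0)
            host_rows.append(
                {
                    "feature_id": f"circ|{gene['gene_id']}",
                    "kind": "circRNA",
                    "category": "circRNA",
                    "expression": cmult * float(rng.lognormal(0.0, 0.5)),
                    "enrichment": float(np.exp(cmu + csd * rng.normal())),
                    "latent": np.nan,
                }
            )

    host = pd.DataFrame(host_rows)
    if len(host):
        host["expression"] *= (1.0 - config.l1_fraction_input if k else 1.0) / host[
            "expression"
        ].sum()
    features = pd.concat([pd.DataFrame(rows), host], ignore_index=True)
    total = features["expression"].sum()
    if total <= 0:
        raise ValueError("zero total expression: nothing to sequence")
    features["p_input"] = features["expression"] / total
    w = features["p_input"] * features["enrichment"]
    features["p_ip"] = w / w.sum()
    return TruthTable(
        features=features,
        theta_l1=pd.Series(theta, index=genome.loci["locus_id"].to_numpy(), name="theta"),
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Paired-end fragments of one library, as code arrays plus origins.

    ``start`` is the fragment start in *transcript* coordinates. For
    circRNA features, positions may wrap around the back-splice junction
    (they index the doubled circle sequence).
    """

    library: str
    read_length: int
    read_ids: np.ndarray  # unicode array
    feature_id: np.ndarray  # unicode array
    start: np.ndarray
    frag_len: np.ndarray
    r1: np.ndarray  # (n, L) codes, fragment 5' mate, forward
    r2: np.ndarray  # (n, L) codes, as sequenced (reverse-complemented)
    junction: np.ndarray  # bool: either mate spans the back-splice junction

    def __len__(self) -> int:
        return len(self.read_ids)

    def origin_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": self.read_ids,
                "library": self.library,
                "feature_id": self.feature_id,
                "start": self.start,
                "frag_len": self.frag_len,
                "junction": self.junction,
            }
        )


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0 or reads.size == 0:
        return
    mask = rng.random(reads.shape) < rate
    shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
    reads[mask] = (reads[mask] + shift[mask]) % 4


def _sample_library(
    name: str,
    genome: SimulatedGenome,
    truth: TruthTable,
    probs: np.ndarray,
    n_reads: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReadSet:
    L = config.read_length
    feats = truth.features
    if n_reads == 0:
        empty = np.empty((0, L), dtype=np.uint8)
        zi = np.empty(0, dtype=np.int64)
        return ReadSet(
            name, L, np.empty(0, dtype="U24"), np.empty(0, dtype="U40"),
            zi, zi, empty, empty.copy(), np.empty(0, dtype=bool),
        )
    choice = rng.choice(len(feats), size=n_reads, p=probs)
    starts = np.zeros(n_reads, dtype=np.int64)
    frags = np.zeros(n_reads, dtype=np.int64)
    r1 = np.zeros((n_reads, L), dtype=np.uint8)
    r2f = np.zeros((n_reads, L), dtype=np.uint8)
    junction = np.zeros(n_reads, dtype=bool)
    arange_l = np.arange(L)
    for fi in np.unique(choice):
        idx = np.flatnonzero(choice == fi)
        row = feats.iloc[fi]
        tseq = genome.transcripts[row["feature_id"]]
        circular = row["kind"] == "circRNA"
        tlen = len(tseq)
        fl = rng.normal(config.fragment_mean, config.fragment_sd, size=len(idx))
        fl = np.clip(np.rint(fl).astype(np.int64), L, max(L, min(tlen, 2 * tlen - L) if circular else tlen))
        if circular:
            doubled = np.concatenate([tseq, tseq])
            st = rng.integers(0, tlen, size=len(idx))
            seqsrc = doubled
            # a mate spans the junction iff its interval crosses index tlen
            e1 = st + L
            s2 = st + fl - L
            junction[idx] = ((st < tlen) & (e1 > tlen)) | ((s2 < tlen) & (s2 + L > tlen))
        else:
            fl = np.minimum(fl, tlen)
            st = rng.integers(0, tlen - fl + 1)
            seqsrc = tseq
        starts[idx] = st
        frags[idx] = fl
        r1[idx] = seqsrc[st[:, None] + arange_l]
        r2f[idx] = seqsrc[(st + fl - L)[:, None] + arange_l]
    _apply_errors(r1, config.sequencing_error_rate, rng)
    _apply_errors(r2f, config.sequencing_error_rate, rng)
    # mate 2 is sequenced from the other end: reverse-complement
    r2 = np.ascontiguousarray(3 - r2f[:, ::-1])
    read_ids = np.array([f"{name}:{i:08d}" for i in range(n_reads)])
    return ReadSet(
        library=name,
        read_length=L,
        read_ids=read_ids,
        feature_id=feats["feature_id"].to_numpy()[choice],
        start=starts,
        frag_len=frags,
        r1=r1,
        r2=r2,
        junction=junction,
    )


def simulate_reads(
    genome: SimulatedGenome, truth: TruthTable, config: SimulationConfig
) -> dict[str, ReadSet]:
    """Draw the paired input and IP libraries.

    Input fragments are drawn feature-proportionally to true expression;
    IP weights are expression x enrichment, renormalised. Per-base errors
    are applied at ``sequencing_error_rate``.
    """
    if truth.features["expression"].sum() <= 0:
        raise ValueError("zero total expression: nothing to sequence")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return {
        "input": _sample_library(
            "input", genome, truth, truth.input_probs, config.n_reads_input, config, rng
        ),
        "ip": _sample_library(
            "ip", genome, truth, truth.ip_probs, config.n_reads_ip, config, rng
        ),
    }


def simulate_count_tables(
    truth: TruthTable,
    n_reads_input: int,
    n_reads_ip: int,
    seed: int,
    replicates: int = 1,
) -> pd.DataFrame:
    """Per-feature read counts for input/IP libraries, drawn multinomially.

    This is the same feature-assignment model as :func:`simulate_reads`
    marginalised over read positions and sequences - the fast path for
    enrichment-statistics work at large library sizes, where per-base
    simulation adds nothing.
    Columns are ``input_1..input_r, ip_1..ip_r``; index is feature_id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    cols = {}
    for r in range(replicates):
        cols[f"input_{r + 1}"] = rng.multinomial(n_reads_input, truth.input_probs)
        cols[f"ip_{r + 1}"] = rng.multinomial(n_reads_ip, truth.ip_probs)
    return pd.DataFrame(cols, index=truth.features["feature_id"].to_numpy())


def simulate_external_tables(
    truth: TruthTable, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Fabricate per-gene p-body / stress-granule enrichment tables.

    Both tables load on the same per-gene latent granule factor that the
    true IP enrichments of polyA genes load on (loading
    ``config.granule_loading``), so the downstream comparison can recover
    a known shared-structure correlation, and partial correlation given
    the p-body vector should largely explain away the stress-granule one.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = truth.features[truth.features["latent"].notna()]
    g = genes["latent"].to_numpy()
    n = len(g)
    pbody = 0.9 * g + math.sqrt(1 - 0.81) * rng.normal(size=n)
    sg = 0.8 * g + math.sqrt(1 - 0.64) * rng.normal(size=n)
    ids = genes["feature_id"].to_numpy()
    return {
        "pbody": pd.DataFrame({"gene_id": ids, "value": pbody, "source": "p-body"}),
        "sg": pd.DataFrame({"gene_id": ids, "value": sg, "source": "SG"}),
    }


# ---------------------------------------------------------------------------
# alignment emulation
# ---------------------------------------------------------------------------


@dataclass
class FragmentHits:
    """All acceptable placements of each fragment, fragment-level.

    One row per (fragment, locus-or-gene) placement, with per-mate mismatch
    counts. ``unmapped`` lists read ids with no acceptable placement
    (e.g. back-splice junction reads, which have no contiguous linear fit).
    """

    library: str
    read_length: int
    hits: pd.DataFrame  # read_id, feature_id, offset, frag_len, nm1, nm2
    unmapped: list[str]


def emulate_alignment(
    reads: ReadSet,
    genome: SimulatedGenome,
    max_mismatches: int = 5,
) -> FragmentHits:
    """Report every placement of each fragment within the mismatch budget.

    LINE-1 fragments are tested against every locus at their consensus
    offset (exact for this generator's substitution-only loci); host
    fragments against their own (unique, random) gene. A mate longer than
    its target or spanning a back-splice junction has no linear placement;
    fragments with no placed mate pair are reported unmapped.
    """
    L = reads.read_length
    arange_l = np.arange(L)
    loci_ids = genome.loci["locus_id"].to_numpy()
    is_l1 = np.isin(reads.feature_id, loci_ids)
    placed = np.zeros(len(reads), dtype=bool)
    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("read_id", "feature_id", "offset", "frag_len", "nm1", "nm2")
    }

    def _emit(sel: np.ndarray, fid: str, st: np.ndarray, m1: np.ndarray, m2: np.ndarray):
        cols["read_id"].append(reads.read_ids[sel])
        cols["feature_id"].append(np.full(sel.size, fid, dtype=object))
        cols["offset"].append(st)
        cols["frag_len"].append(reads.frag_len[sel])
        cols["nm1"].append(m1)
        cols["nm2"].append(m2)
        placed[sel] = True

    if is_l1.any():
        lmat = genome.locus_matrix()
        idx = np.flatnonzero(is_l1)
        st = reads.start[idx]
        en = st + reads.frag_len[idx] - L
        r1 = reads.r1[idx]
        r2f = np.ascontiguousarray(3 - reads.r2[idx, ::-1])  # back to forward strand
        i1 = st[:, None] + arange_l
        i2 = en[:, None] + arange_l
        for j, locus_id in enumerate(loci_ids):
            m1 = (lmat[j][i1] != r1).sum(axis=1)
            m2 = (lmat[j][i2] != r2f).sum(axis=1)
            ok = (m1 <= max_mismatches) & (m2 <= max_mismatches)
            k = np.flatnonzero(ok)
            if k.size:
                _emit(idx[k], str(locus_id), st[k], m1[k], m2[k])

    hidx = np.flatnonzero(~is_l1)
    if hidx.size:
        feats = reads.feature_id[hidx]
        for fid in np.unique(feats):
            sel = hidx[feats == fid]
            sel = sel[~reads.junction[sel]]  # junction reads have no linear fit
            if sel.size == 0:
                continue
            tseq = genome.transcripts[fid]
            tlen = len(tseq)
            st = reads.start[sel] % tlen if fid.startswith("circ|") else reads.start[sel]
            en = st + reads.frag_len[sel] - L
            good = en + L <= tlen  # guards a circ wrap without a junction mate
            sel, st, en = sel[good], st[good], en[good]
            if sel.size == 0:
                continue
            r2f = np.ascontiguousarray(3 - reads.r2[sel, ::-1])
            m1 = (tseq[st[:, None] + arange_l] != reads.r1[sel]).sum(axis=1)
            m2 = (tseq[en[:, None] + arange_l] != r2f).sum(axis=1)
            ok = (m1 <= max_mismatches) & (m2 <= max_mismatches)
            k = np.flatnonzero(ok)
            if k.size:
                _emit(sel[k], str(fid), st[k], m1[k], m2[k])

    if cols["read_id"]:
        hits = pd.DataFrame(
            {
                "read_id": np.concatenate(cols["read_id"]),
                "feature_id": np.concatenate(cols["feature_id"]),
                "offset": np.concatenate(cols["offset"]).astype(np.int64),
                "frag_len": np.concatenate(cols["frag_len"]).astype(np.int64),
                "nm1": np.concatenate(cols["nm1"]).astype(np.int64),
                "nm2": np.concatenate(cols["nm2"]).astype(np.int64),
            }
        )
    else:
        hits = pd.DataFrame(
            columns=["read_id", "feature_id", "offset", "frag_len", "nm1", "nm2"]
        )
    unmapped = [str(r) for r in reads.read_ids[~placed]]
    return FragmentHits(
        library=reads.library, read_length=L, hits=hits, unmapped=unmapped
    )


def hits_to_genomic(hits: FragmentHits, genome: SimulatedGenome) -> pd.DataFrame:
    """Add chromosome coordinates (0-based fragment start/end) to hit rows.

    For minus-strand loci the transcript offset is measured from the
    genomic *end* of the element.
    """
    lut_rows = [
        (r["locus_id"], int(r["start"]), int(r["end"]), r["strand"])
        for _, r in genome.loci.iterrows()
    ]
    for _, r in genome.genes.iterrows():
        lut_rows.append((r["gene_id"], int(r["start"]), int(r["end"]), "+"))
        if r["circ_start"] >= 0:
            lut_rows.append(
                (f"circ|{r['gene_id']}", int(r["circ_start"]), int(r["circ_end"]), "+")
            )
    lut = pd.DataFrame(lut_rows, columns=["feature_id", "f_start", "f_end", "f_strand"])
    out = hits.hits.merge(lut, on="feature_id", how="left", validate="m:1")
    minus = (out["f_strand"] == "-").to_numpy()
    g_start = np.where(
        minus,
        out["f_end"].to_numpy() - out["offset"].to_numpy() - out["frag_len"].to_numpy(),
        out["f_start"].to_numpy() + out["offset"].to_numpy(),
    )
    out["chrom"] = genome.chrom
    out["g_start"] = g_start.astype(np.int64)
    out["g_end"] = (g_start + out["frag_len"].to_numpy()).astype(np.int64)
    return out.drop(columns=["f_start", "f_end", "f_strand"])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_fasta(path: Path, records: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def write_fastq_pair(prefix: Path, reads: ReadSet) -> tuple[Path, Path]:
    """Write mate FASTQ files `<prefix>_R1.fastq` / `<prefix>_R2.fastq`."""
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    qual = "I" * reads.read_length
    for path, mat in ((p1, reads.r1), (p2, reads.r2)):
        with open(path, "w") as fh:
            for rid, row in zip(reads.read_ids, mat):
                fh.write(f"@{rid}\n{decode(row)}\n+\n{qual}\n")
    return p1, p2


def write_bed(path: Path, genome: SimulatedGenome) -> None:
    with open(path, "w") as fh:
        for _, r in genome.loci.iterrows():
            fh.write(
                f"{genome.chrom}\t{r['start']}\t{r['end']}\t"
                f"{r['locus_id']}\t0\t{r['strand']}\n"
            )


def write_gtf(path: Path, genome: SimulatedGenome) -> None:
    """Genes/exons (and back-splice junctions) in 1-based inclusive GTF."""
    with open(path, "w") as fh:
        for _, r in genome.genes.iterrows():
            attrs = (
                f'gene_id "{r["gene_id"]}"; category "{r["category"]}";'
            )
            for kind in ("gene", "exon"):
                fh.write(
                    f"{genome.chrom}\tl1ripseq\t{kind}\t{r['start'] + 1}\t{r['end']}\t"
                    f".\t{r['strand']}\t.\t{attrs}\n"
                )
            if r["circ_start"] >= 0:
                fh.write(
                    f"{genome.chrom}\tl1ripseq\tbacksplice\t{r['circ_start'] + 1}\t"
                    f"{r['circ_end']}\t.\t{r['strand']}\t.\t{attrs}\n"
                )


def write_sam(path: Path, hits: FragmentHits, genome: SimulatedGenome) -> None:
    """Serialise fragment hits as multi-hit paired SAM records.

    The best placement per fragment (fewest total mismatches, ties to the
    first feature in annotation order) is primary; others are secondary.
    Unmapped fragments get a flag-4 record so every simulated read is
    accounted for.
    """
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": genome.chrom, "LN": int(len(genome.seq))}],
        }
    )
    g = hits_to_genomic(hits, genome)
    L = hits.read_length
    strand = (
        g["feature_id"].map(genome.loci.set_index("locus_id")["strand"]).fillna("+")
    )
    g = g.assign(nm=g["nm1"] + g["nm2"], minus=(strand == "-").to_numpy())
    g = g.sort_values(["read_id", "nm", "feature_id"], kind="stable")
    rank = g.groupby("read_id", sort=False).cumcount().to_numpy()
    nhits = g.groupby("read_id", sort=False)["nm"].transform("size").to_numpy()
    sec = np.where(rank > 0, 256, 0)
    minus = g["minus"].to_numpy()
    # transcript mate1 sits at the genomic end of minus-strand loci
    pos1 = np.where(minus, g["g_end"].to_numpy() - L, g["g_start"].to_numpy())
    pos2 = np.where(minus, g["g_start"].to_numpy(), g["g_end"].to_numpy() - L)
    f1 = (0x1 | 0x2 | 0x40) | sec | np.where(minus, 0x10, 0x20)
    f2 = (0x1 | 0x2 | 0x80) | sec | np.where(minus, 0x20, 0x10)
    mapq = np.where(nhits > 1, 0, 60)
    rid = g["read_id"].to_numpy()
    nm1 = g["nm1"].to_numpy()
    nm2 = g["nm2"].to_numpy()
    chrom, cig = genome.chrom, f"{L}M"
    with open(path, "w") as out:
        out.write(str(header))
        for i in range(len(g)):
            out.write(
                f"{rid[i]}\t{f1[i]}\t{chrom}\t{pos1[i] + 1}\t{mapq[i]}\t{cig}"
                f"\t=\t{pos2[i] + 1}\t0\t*\t*\tNM:i:{nm1[i]}\n"
                f"{rid[i]}\t{f2[i]}\t{chrom}\t{pos2[i] + 1}\t{mapq[i]}\t{cig}"
                f"\t=\t{pos1[i] + 1}\t0\t*\t*\tNM:i:{nm2[i]}\n"
            )
        for urid in sorted(hits.unmapped):
            out.write(f"{urid}\t77\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")


def write_truth(outdir: Path, truth: TruthTable) -> None:
    truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)
    truth.theta_l1.rename_axis("locus_id").to_csv(
        outdir / "truth_theta.tsv", sep="\t"
    )


def simulate_all(config: SimulationConfig, outdir: Path | None = None):
    """Run the full generator; optionally write all standard-format outputs.

    Returns (genome, truth, reads, hits-per-library).
    """
    genome = simulate_genome(config)
    truth = simulate_truth(genome, config)
    reads = simulate_reads(genome, truth, config)
    hits = {name: emulate_alignment(rs, genome) for name, rs in reads.items()}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", {genome.chrom: genome.seq_str})
        write_fasta(
            outdir / "consensus_proteins.fa",
            {"ORF1p": genome.orf1_protein, "ORF2p": genome.orf2_protein},
        )
        write_bed(outdir / "l1_loci.bed", genome)
        write_gtf(outdir / "genes.gtf", genome)
        write_truth(outdir, truth)
        for name, rs in reads.items():
            write_fastq_pair(outdir / name, rs)
            rs.origin_table().to_csv(
                outdir / f"{name}_origins.tsv", sep="\t", index=False
            )
            write_sam(outdir / f"{name}.sam", hits[name], genome)
        with open(outdir / "config.json", "w") as fh:
            import json

            json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
    return genome, truth, reads, hits
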