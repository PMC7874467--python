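"""ORF discovery and intactness classification of LINE-1 loci.

A LINE-1 copy is transcriptionally competent for retrotransposition only
if its two open reading frames still encode (near) full-length proteins:
ORF1p, the RNA-binding chaperone, and ORF2p, the endonuclease/reverse
transcriptase. This module finds candidate ORFs on the sense strand of a
locus, aligns their translations to ORF1p/ORF2p consensus proteins by
local alignment, and calls an ORF intact when the alignment spans at
least 95% of the consensus (``threshold=0.95``). Loci fall into three
classes: fully intact, ORF1-intact/ORF2-truncated, and ORF1-truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .simulate import CLASSES, FULLY_INTACT, ORF1_INTACT_ORF2_TRUNC, ORF1_TRUNC

__all__ = [
    "OrfCandidate",
    "ConsensusCoverage",
    "IntactnessCall",
    "find_orfs",
    "align_to_consensus",
    "classify_locus",
    "classify_panel",
]

_DNA_RE = re.compile(r"^[ACGTNacgtn]*$")


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG-to-stop open reading frame on the sense strand."""

    locus_id: str
    frame: int  # 0-2
    start: int  # nt, 0-based half-open within the locus, includes the stop
    end: int
    protein: str  # translated, stop excluded

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class ConsensusCoverage:
    """How much of a consensus protein one candidate's alignment spans.

    ``coverage`` counts the consensus span between the first and last
    aligned consensus positions (internal gaps included) over the
    consensus length.
    """

    target: str  # "ORF1" | "ORF2"
    span: int  # aligned consensus span, aa
    coverage: float
    score: float


@dataclass(frozen=True)
class IntactnessCall:
    locus_id: str
    orf1_intact: bool
    orf2_intact: bool
    orf1_coverage: float
    orf2_coverage: float

    @property
    def intact_class(self) -> str:
        if not self.orf1_intact:
            return ORF1_TRUNC
        return FULLY_INTACT if self.orf2_intact else ORF1_INTACT_ORF2_TRUNC


def find_orfs(
    locus_sequence: str,
    locus_id: str = "",
    min_orf_aa: int = 300,
    require_atg: bool = True,
) -> list[OrfCandidate]:
    """All maximal sense-strand ORFs strictly longer than ``min_orf_aa``.

    In each of the three forward frames, every stop-to-stop segment
    contributes at most one candidate: from its first ATG (or from the
    segment start when ``require_atg`` is False, useful for heavily
    diverged elements) to the stop. Sorted by start position. A sequence
    too short to host a qualifying ORF simply yields an empty list.
    """
    seq = locus_sequence.upper()
    if not _DNA_RE.match(seq):
        raise ValueError("locus sequence must contain only A/C/G/T/N")
    out: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        aa = str(Seq(seq[frame : frame + (n - frame) // 3 * 3]).translate())
        seg_start = 0  # codon index where current stop-free segment starts
        for match in re.finditer(r"\*", aa + "*"):
            seg_end = match.start()
            segment = aa[seg_start:seg_end]
            first = segment.find("M") if require_atg else 0
            if first >= 0:
                protein = segment[first:]
                if len(protein) > min_orf_aa:
                    codon0 = seg_start + first
                    nt_start = frame + 3 * codon0
                    nt_end = frame + 3 * (seg_end + 1)  # include stop codon
                    out.append(
                        OrfCandidate(
                            locus_id=locus_id,
                            frame=frame,
                            start=nt_start,
                            end=min(nt_end, n),
                            protein=protein,
                        )
                    )
            seg_start = seg_end + 1
    out.sort(key=lambda c: (c.start, c.frame))
    return out


_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_to_consensus(
    protein: str,
    consensus_protein: str,
    target: str = "",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ConsensusCoverage:
    """Local-align a candidate protein to a consensus protein.

    BLOSUM62 with affine gaps (defaults mirror blastp conventions).
    Coverage is the consensus span of the best local alignment divided by
    the consensus length.
    """
    for name, s in (("protein", protein), ("consensus", consensus_protein)):
        if not s:
            raise ValueError(f"{name} sequence is empty")
        bad = set(s.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {bad}")
    aligner = _aligner(gap_open, gap_extend)
    alignment = aligner.align(consensus_protein.upper(), protein.upper())[0]
    tstart = int(alignment.aligned[0][0][0])
    tend = int(alignment.aligned[0][-1][1])
    span = tend - tstart
    return ConsensusCoverage(
        target=target,
        span=span,
        coverage=span / len(consensus_protein),
        score=float(alignment.score),
    )


def classify_locus(
    locus_id: str,
    orf_candidates: list[OrfCandidate],
    orf1_consensus: str,
    orf2_consensus: str,
    threshold: float = 0.95,
) -> IntactnessCall:
    """Call ORF1/ORF2 intactness for one locus.

    An ORF is intact iff some candidate's local alignment covers at least
    ``threshold`` of that consensus protein. A locus with no candidates is
    ORF1-truncated by definition.
    """
    best1 = best2 = 0.0
    for cand in orf_candidates:
        best1 = max(best1, align_to_consensus(cand.protein, orf1_consensus, "ORF1").coverage)
        best2 = max(best2, align_to_consensus(cand.protein, orf2_consensus, "ORF2").coverage)
    return IntactnessCall(
        locus_id=locus_id,
        orf1_intact=best1 >= threshold,
        orf2_intact=best2 >= threshold,
        orf1_coverage=best1,
        orf2_coverage=best2,
    )


def classify_panel(
    locus_sequences: dict[str, str],
    orf1_consensus: str,
    orf2_consensus: str,
    min_orf_aa: int = 300,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Classify a panel of loci; one row per locus.

    Columns: locus_id, intact_class, orf1_intact, orf2_intact,
    orf1_coverage, orf2_coverage, n_candidates.
    """
    rows = []
    for locus_id, seq in locus_sequences.items():
        cands = find_orfs(seq, locus_id, min_orf_aa=min_orf_aa)
        call = classify_locus(locus_id, cands, orf1_consensus, orf2_consensus, threshold)
        rows.append(
            {
                "locus_id": locus_id,
                "intact_class": call.intact_class,
                "orf1_intact": call.orf1_intact,
                "orf2_intact": call.orf2_intact,
                "orf1_coverage": call.orf1_coverage,
                "orf2_coverage": call.orf2_coverage,
                "n_candidates": len(cands),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "intact_class",
            "orf1_intact",
            "orf2_intact",
            "orf1_coverage",
            "orf2_coverage",
            "n_candidates",
        ],
    )
    df["intact_class"] = pd.Categorical(df["intact_class"], categories=list(CLASSES))
    return df


def extract_locus_sequences(genome_fasta: Path, loci_bed: Path) -> dict[str, str]:
    """Pull locus sequences (strand-adjusted) from a genome FASTA + BED."""
    from Bio import SeqIO

    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    out = {}
    bed = pd.read_csv(
        loci_bed,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    for _, r in bed.iterrows():
        seq = chroms[r["chrom"]][int(r["start"]) : int(r["end"])]
        if r["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
        out[str(r["name"])] = seq
    return out


def read_single_fasta(path: Path) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(str(path), "fasta")).seq)
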