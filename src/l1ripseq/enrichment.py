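"""IP-vs-input enrichment estimation and library-level summaries.

RIP-seq enrichment of a transcript is its normalized abundance in the
immunoprecipitate relative to the matched input lysate. Libraries are
made comparable by median-of-ratios size factors (each sample's median
ratio of counts to the featurewise geometric mean); per-feature fold
enrichment is then the ratio of mean normalized counts with a small
pseudocount, with a two-sided test of equal proportions and
Benjamini-Hochberg FDR attached. Category-level summaries (median fold
enrichment, rank-sum test against the complement) reproduce the
stratified view: LINE-1 intactness classes, histone-like non-polyA
genes, mitochondrial RNA, lncRNA, pooled circRNA, and so on.

Also here: hierarchical read-category fractions (rRNA -> exon -> LINE-1
-> other, first match wins, mirroring a filter-then-count workflow),
pooling of back-splice junction reads into a single circRNA feature,
Jaccard overlap of expressed-locus sets with a Welch one-sided t-test,
and the delta-delta-Ct helper for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .granules import bh_fdr

__all__ = [
    "count_read_categories",
    "pool_circ_reads",
    "size_factors",
    "fold_enrichment",
    "category_summary",
    "locus_set_overlap",
    "ddct",
]

CATEGORY_ORDER = ("rRNA", "exon", "L1", "other")


def count_read_categories(
    positions: pd.DataFrame, annotations: pd.DataFrame
) -> pd.Series:
    """Fractions of fragments in {rRNA, exon, L1, other}.

    ``positions`` has one row per fragment with columns chrom, start, end
    (0-based half-open; unmapped fragments may carry start < 0 and count
    as "other"). ``annotations`` has chrom, start, end, category with
    category in {rRNA, exon, L1}. Assignment is hierarchical in the fixed
    order rRNA -> exon -> L1 -> other: a fragment overlapping an rRNA
    interval is rRNA regardless of any other overlap, then exon, then L1.
    Fractions sum to exactly 1.
    """
    n = len(positions)
    if n == 0:
        raise ValueError("no fragments to categorise")
    assigned = np.full(n, "other", dtype=object)
    remaining = np.ones(n, dtype=bool)
    mapped = (positions["start"].to_numpy() >= 0) & (
        positions["end"].to_numpy() > positions["start"].to_numpy()
    )
    remaining &= mapped
    for cat in CATEGORY_ORDER[:3]:
        ann = annotations[annotations["category"] == cat]
        if len(ann) == 0 or not remaining.any():
            continue
        hit = np.zeros(n, dtype=bool)
        for chrom, sub in ann.groupby("chrom"):
            sel = remaining & (positions["chrom"].to_numpy() == chrom)
            if not sel.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
            # overlap with any interval: the interval starting at or before
            # the fragment end must end after the fragment start
            idx = np.searchsorted(starts, positions["end"].to_numpy()[sel], side="left") - 1
            ok = idx >= 0
            ok[ok] = ends[idx[ok]] > positions["start"].to_numpy()[sel][ok]
            hit[np.flatnonzero(sel)[ok]] = True
        assigned[hit] = cat
        remaining &= ~hit
    frac = pd.Series(assigned).value_counts() / n
    return frac.reindex(CATEGORY_ORDER, fill_value=0.0)


def pool_circ_reads(junction_read_counts) -> int:
    """Pool per-junction back-splice read counts into one circRNA count."""
    vals = np.asarray(list(junction_read_counts), dtype=np.int64)
    return int(vals.sum()) if vals.size else 0


@dataclass
class SampleNormalization:
    """Median-of-ratios size factors, one per sample (geometric mean ~ 1)."""

    factors: pd.Series

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def size_factors(counts: pd.DataFrame) -> SampleNormalization:
    """Median-of-ratios size factors.

    For each sample k: s_k = median over features f of
    count_fk / geomean_f, where geomean_f is the geometric mean of
    feature f across samples, computed over features positive in every
    sample. Requires >= 2 samples and at least one all-positive feature.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need >= 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature is positive in all samples; add a pseudocount or "
            "filter samples before normalising"
        )
    sub = counts.loc[positive].astype(float)
    log_geomean = np.log(sub).mean(axis=1)
    # median taken on the ratio scale (an even feature count averages the
    # two central ratios, not their logs)
    ratios = np.exp(np.log(sub).sub(log_geomean, axis=0))
    s = ratios.median(axis=0)
    return SampleNormalization(factors=s)


def total_count_factors(
    counts: pd.DataFrame, denominator_features=None
) -> SampleNormalization:
    """Size factors proportional to per-sample totals ("all aligned reads").

    Optionally restrict the denominator to a feature subset (e.g. exonic
    genes only, mimicking pipelines that normalise to exon-aligned reads;
    the choice changes the *scale* of every fold enrichment). Factors are
    rescaled to geometric mean 1.
    """
    sub = counts if denominator_features is None else counts.loc[denominator_features]
    totals = sub.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive denominator total")
    s = totals / np.exp(np.log(totals).mean())
    return SampleNormalization(factors=s)


def fold_enrichment(
    counts: pd.DataFrame,
    ip_samples: list[str],
    input_samples: list[str],
    normalization: SampleNormalization | None = None,
    pseudocount: float = 0.5,
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature IP/input fold enrichment with test statistics.

    Counts are divided by their sample's size factor, then expressed per
    million of the (geometric-mean) normalized library size, which makes
    every fold enrichment exactly invariant to rescaling any one
    library's counts. E = mean over IP samples of (normalized +
    pseudocount) over the same for input; the pseudocount (default 0.5
    per million) tames zero-input features. The per-feature p-value is a
    two-sided two-proportion z-test of the feature's share of its library
    between the pooled IP and pooled input counts when each group has one
    sample; with replicates it is a rank-sum test across the
    per-replicate normalized values. BH-adjusted FDR is attached.
    """
    for name, group in (("ip", ip_samples), ("input", input_samples)):
        if not group:
            raise ValueError(f"missing {name} sample group")
        missing = [s for s in group if s not in counts.columns]
        if missing:
            raise ValueError(f"unknown {name} samples: {missing}")
    if normalization is None:
        normalization = size_factors(counts[list(ip_samples) + list(input_samples)])
    s = normalization.factors
    norm = counts / s
    lib = norm[list(ip_samples) + list(input_samples)].sum(axis=0)
    norm = norm / np.exp(np.log(lib).mean()) * 1e6
    ip_mean = norm[ip_samples].mean(axis=1) + pseudocount
    input_mean = norm[input_samples].mean(axis=1) + pseudocount
    E = ip_mean / input_mean

    if len(ip_samples) == 1 and len(input_samples) == 1:
        p = _two_proportion_p(
            counts[ip_samples[0]].to_numpy(), counts[input_samples[0]].to_numpy()
        )
    else:
        p = _replicate_ranksum_p(norm, ip_samples, input_samples)
    out = pd.DataFrame(
        {
            "feature_id": counts.index,
            "ip_mean": ip_mean.to_numpy(),
            "input_mean": input_mean.to_numpy(),
            "enrichment": E.to_numpy(),
            "log2_enrichment": np.log2(E.to_numpy()),
            "p_value": p,
        }
    ).set_index("feature_id")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    if categories is not None:
        out.insert(0, "category", categories.reindex(out.index))
    return out


def _two_proportion_p(x_ip: np.ndarray, x_in: np.ndarray) -> np.ndarray:
    """Two-sided z-test that a feature's library share is equal in IP and
    input (pooled-variance normal approximation), vectorised over features."""
    n_ip = x_ip.sum()
    n_in = x_in.sum()
    if n_ip == 0 or n_in == 0:
        return np.ones(len(x_ip))
    p1 = x_ip / n_ip
    p2 = x_in / n_in
    pooled = (x_ip + x_in) / (n_ip + n_in)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_ip + 1 / n_in))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def _replicate_ranksum_p(
    norm: pd.DataFrame, ip_samples: list[str], input_samples: list[str]
) -> np.ndarray:
    p = np.ones(len(norm))
    ip = norm[ip_samples].to_numpy()
    inp = norm[input_samples].to_numpy()
    for i in range(len(norm)):
        try:
            p[i] = stats.mannwhitneyu(ip[i], inp[i], alternative="two-sided").pvalue
        except ValueError:  # all identical
            p[i] = 1.0
    return p


def category_summary(
    records: pd.DataFrame, category: str, value_col: str = "enrichment"
) -> dict:
    """Median/quartiles of fold enrichment within a category plus a
    two-sample rank-sum (Mann-Whitney) comparison against all other
    features (two-sided; exact when both groups have n <= 12 and no ties,
    normal approximation with tie correction otherwise)."""
    if "category" not in records.columns:
        raise ValueError("records must carry a 'category' column")
    mask = records["category"] == category
    x = records.loc[mask, value_col].to_numpy()
    y = records.loc[~mask, value_col].to_numpy()
    if len(x) == 0:
        raise ValueError(f"empty category: {category}")
    out = {
        "category": category,
        "n": int(len(x)),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
    }
    if len(y):
        method = "exact" if (len(x) <= 12 and len(y) <= 12) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out["ranksum_stat"] = float(res.statistic)
        out["ranksum_p"] = float(res.pvalue)
    else:
        out["ranksum_stat"] = np.nan
        out["ranksum_p"] = np.nan
    return out


def expressed_loci(
    estimate_counts: pd.Series, total_l1_reads: int | None = None, floor_per_million: float = 1.0
) -> set[str]:
    """Loci whose expected count clears the expression floor
    (default: 1 expected fragment per million LINE-1 fragments)."""
    total = total_l1_reads if total_l1_reads is not None else float(estimate_counts.sum())
    floor = floor_per_million * total / 1e6
    return set(estimate_counts.index[estimate_counts >= max(floor, 0.0)])


def locus_set_overlap(
    expressed_sets: dict[str, set],
    pairs_within: list[tuple[str, str]],
    pairs_between: list[tuple[str, str]],
) -> dict:
    """Pairwise Jaccard overlaps (as percentages) between expressed-locus
    sets, and a Welch one-sided t-test that within-family overlaps exceed
    between-family overlaps."""

    def jaccard(a: set, b: set) -> float:
        if not a and not b:
            return 100.0
        return 100.0 * len(a & b) / len(a | b)

    for name, s in expressed_sets.items():
        if not s:
            raise ValueError(f"expressed-locus set {name!r} is empty")
    within = [jaccard(expressed_sets[a], expressed_sets[b]) for a, b in pairs_within]
    between = [jaccard(expressed_sets[a], expressed_sets[b]) for a, b in pairs_between]
    out = {
        "overlap_within": within,
        "overlap_between": between,
    }
    if len(within) >= 2 and len(between) >= 2:
        res = stats.ttest_ind(within, between, equal_var=False, alternative="greater")
        out["t_stat"] = float(res.statistic)
        out["t_p"] = float(res.pvalue)
    else:
        out["t_stat"] = None
        out["t_p"] = None
        out["note"] = "t-test undefined: fewer than 2 overlap values in a group"
    return out


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold by delta-delta-Ct: 2^-ddCt with
    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control."""
    ddct_val = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct_val))
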