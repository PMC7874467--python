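"""Comparison of RIP enrichments with external RNA-granule tables.

Whether the transcripts pulled down with ORF1p look like the p-body or
the stress-granule transcriptome is asked two ways: as a rank
correlation between per-gene enrichment vectors (Spearman, and partial
Spearman to control for the strong p-body/stress-granule similarity),
and as a 2x2 overlap between the FDR-gated enriched gene sets (odds
ratio with a one-sided exact hypergeometric test). The building blocks -
step-up Benjamini-Hochberg adjustment, tie-aware Spearman with exact
small-n permutation p-values, the partial-correlation recursion, and the
exact overlap test - are implemented here and cross-checked against
independent oracles in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bh_fdr",
    "overlap_test",
    "spearman",
    "partial_spearman",
    "join_and_compare",
    "ComparisonStats",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class OverlapResult:
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p_value: float
    haldane_corrected: bool
    log10_p: float


def overlap_test(
    set_a: set, set_b: set, universe: set, alternative: str = "greater"
) -> OverlapResult:
    """2x2 overlap of two gene sets within a universe.

    a=|A&B|, b=|A-B|, c=|B-A|, d=|universe-(A|B)|; OR = ad/bc with a
    Haldane 0.5 correction (flagged) when any cell is zero. The p-value
    is the exact hypergeometric tail in the requested direction
    (default: enrichment), evaluated in log space so that very small
    values survive; ``log10_p`` is reported alongside and never floors
    to zero.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    corrected = 0 in (a, b, c, d)
    if corrected:
        oa, ob, oc, od = (x + 0.5 for x in (a, b, c, d))
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    M, K, N = len(universe), a + b, a + c
    logp = hypergeom_tail_logp(a, M, K, N, alternative, table=(a, b, c, d))
    return OverlapResult(
        table=(a, b, c, d),
        odds_ratio=float(odds),
        p_value=float(math.exp(logp)),
        haldane_corrected=corrected,
        log10_p=logp / math.log(10.0),
    )


def hypergeom_tail_logp(
    a, M: int, K: int, N: int, alternative: str = "greater", table=None
):
    """Natural-log p-value of the exact overlap test.

    Under the null, the overlap count of two fixed-size sets drawn from a
    universe of M is Hypergeom(M, K, N); "greater" sums the upper tail
    P(X >= a) in log space so extreme significances do not floor to 0.
    Accepts array ``a``.
    """
    if alternative == "greater":
        logp = stats.hypergeom.logsf(np.asarray(a) - 1, M, K, N)
    elif alternative == "less":
        logp = stats.hypergeom.logcdf(a, M, K, N)
    elif alternative == "two-sided":
        if table is None:
            raise ValueError("two-sided mode needs the full 2x2 table")
        ta, tb, tc, td = table
        logp = math.log(max(stats.fisher_exact([[ta, tb], [tc, td]]).pvalue, 5e-324))
    else:
        raise ValueError(f"unknown alternative: {alternative}")
    return np.minimum(logp, 0.0) if np.ndim(a) else float(min(logp, 0.0))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Tie-aware Spearman correlation with its two-sided p-value.

    rho is the Pearson correlation of midranks. The p-value comes from
    full permutation enumeration for n <= ``exact_max_n`` (counting
    permutations with |rho| at least as extreme) and from the standard
    t approximation with n-2 degrees of freedom otherwise. A constant
    vector leaves rho undefined (NaN, p = NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for z.

    Uses the first-order recursion on tie-aware rank correlations:
    rho_xy.z = (rho_xy - rho_xz rho_yz) / sqrt((1-rho_xz^2)(1-rho_yz^2)),
    with a t approximation on n-3 degrees of freedom for the p-value.
    Undefined (NaN) when either controlling correlation is +-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    rx, ry, rz = _midranks(x), _midranks(y), _midranks(z)
    rxy = float(np.corrcoef(rx, ry)[0, 1])
    rxz = float(np.corrcoef(rx, rz)[0, 1])
    ryz = float(np.corrcoef(ry, rz)[0, 1])
    denom = (1 - rxz**2) * (1 - ryz**2)
    if denom <= 1e-12:  # |rho_xz| or |rho_yz| is (numerically) 1
        return float("nan"), float("nan")
    rho = (rxy - rxz * ryz) / math.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    t = rho * math.sqrt(df / max(1e-300, 1.0 - rho * rho))
    p = float(min(2 * stats.t.sf(abs(t), df=df), 1.0))
    return rho, p


@dataclass
class ComparisonStats:
    """Joined comparison of IP enrichment against one external vector."""

    n_joined: int
    n_discarded: int
    spearman_rho: float
    spearman_p: float
    overlap: OverlapResult
    partial_rho: float | None = None
    partial_p: float | None = None
    joined: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_dict(self) -> dict:
        out = {
            "n_joined": self.n_joined,
            "n_discarded": self.n_discarded,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "odds_ratio": self.overlap.odds_ratio,
            "overlap_p": self.overlap.p_value,
            "overlap_log10_p": self.overlap.log10_p,
            "table": list(self.overlap.table),
            "haldane_corrected": self.overlap.haldane_corrected,
        }
        if self.partial_rho is not None:
            out["partial_rho"] = self.partial_rho
            out["partial_p"] = self.partial_p
        return out


def join_and_compare(
    enrichment: pd.DataFrame,
    external: pd.DataFrame,
    external2: pd.DataFrame | None = None,
    fdr_gate: float = 0.05,
    external_gate: float = 0.0,
    min_join: int = 10,
) -> ComparisonStats:
    """Join per-gene IP enrichments with an external enrichment table and
    compute the comparison statistics.

    ``enrichment`` is indexed by feature/gene id with columns
    log2_enrichment and fdr (the output of fold_enrichment);
    ``external`` has gene_id and value columns. The 2x2 overlap compares
    genes at IP FDR < ``fdr_gate`` (enriched direction) against genes
    with external value > ``external_gate``, within the universe of
    joined genes. With ``external2`` given, the partial Spearman of IP
    vs external controlling for external2 is added.
    """
    ext = external.set_index("gene_id")["value"]
    joined = enrichment.join(ext.rename("external"), how="inner")
    joined = joined.dropna(subset=["external", "log2_enrichment"])
    n_discarded = len(enrichment) - len(joined)
    if len(joined) < min_join:
        raise ValueError(
            f"only {len(joined)} genes joined (< {min_join}); "
            f"enrichment ids look like {list(enrichment.index[:3])}, "
            f"external ids like {list(external['gene_id'][:3])}"
        )
    rho, p = spearman(joined["log2_enrichment"], joined["external"])
    universe = set(joined.index)
    ip_set = set(
        joined.index[(joined["fdr"] < fdr_gate) & (joined["log2_enrichment"] > 0)]
    )
    ext_set = set(joined.index[joined["external"] > external_gate])
    ov = overlap_test(ip_set, ext_set, universe)
    partial_rho = partial_p = None
    if external2 is not None:
        ext2 = external2.set_index("gene_id")["value"].rename("external2")
        j2 = joined.join(ext2, how="inner").dropna(subset=["external2"])
        if len(j2) >= min_join:
            partial_rho, partial_p = partial_spearman(
                j2["log2_enrichment"], j2["external"], j2["external2"]
            )
    return ComparisonStats(
        n_joined=len(joined),
        n_discarded=n_discarded,
        spearman_rho=rho,
        spearman_p=p,
        overlap=ov,
        partial_rho=partial_rho,
        partial_p=partial_p,
        joined=joined,
    )
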