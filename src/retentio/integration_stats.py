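"""Joining differential IR to expression changes, plus set statistics.

Expression fold changes come from a simple median-of-ratios normalization
with a pseudocounted log2 ratio of condition means (an externally supplied
log2FC table is accepted verbatim by the pipeline).  Per-gene mean delta-IR
is length-weighted over the gene's reliable differential events.  Overlap
tests are one-sided hypergeometric upper tails (equivalently Fisher's exact
on the 2x2 table); preranked GSEA uses the weighted Kolmogorov-Smirnov
running sum with gene-set permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ir_core import DifferentialIREvent

QUADRANTS = {
    (-1, 1): "IR_down_E_up",
    (-1, -1): "IR_down_E_down",
    (1, 1): "IR_up_E_up",
    (1, -1): "IR_up_E_down",
}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    per-gene geometric mean, over genes expressed in every sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(log_ratios.median(axis=0))


def normalize_and_lfc(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Normalized condition means and log2 fold change (A vs B) per gene.

    All-zero genes are excluded.  When both conditions have >= 2 replicates
    a naive two-sample t-test on log-normalized counts provides an internal
    significance p-value (external FDR tables can be joined instead).
    """
    counts = counts.loc[(counts.sum(axis=1) > 0)]
    if counts.empty:
        raise ValueError("count matrix has no expressed genes")
    size_factors = median_of_ratios_size_factors(counts)
    normalized = counts.div(size_factors, axis=1)
    mean_a = normalized[list(samples_a)].mean(axis=1)
    mean_b = normalized[list(samples_b)].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    result = pd.DataFrame(
        {
            "gene_id": counts.index,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2fc": lfc.to_numpy(),
        }
    )
    if len(samples_a) >= 2 and len(samples_b) >= 2:
        log_a = np.log2(normalized[list(samples_a)] + pseudocount)
        log_b = np.log2(normalized[list(samples_b)] + pseudocount)
        _, pvals = stats.ttest_ind(log_a, log_b, axis=1)
        result["p_value"] = pvals
    else:
        result["p_value"] = np.nan
    return result.reset_index(drop=True)


# ---------------------------------------------------------------------------
# integration of delta-IR with expression
# ---------------------------------------------------------------------------


def gene_mean_delta_ir(
    deltas: Sequence[float], intron_lengths: Sequence[float]
) -> float:
    """Length-weighted mean delta-IR: sum(delta_i * L_i) / sum(L_i)."""
    deltas = np.asarray(deltas, dtype=float)
    lengths = np.asarray(intron_lengths, dtype=float)
    if deltas.size == 0:
        raise ValueError("at least one event required")
    if deltas.size != lengths.size:
        raise ValueError("deltas and lengths must align")
    return float(np.sum(deltas * lengths) / np.sum(lengths))


def _quadrant(delta: float, lfc: float) -> str:
    if delta == 0 or lfc == 0 or not np.isfinite(delta) or not np.isfinite(lfc):
        return "unclassified"
    return QUADRANTS[(int(np.sign(delta)), int(np.sign(lfc)))]


@dataclass
class IntegrationResult:
    records: pd.DataFrame  # one row per gene
    per_event: pd.DataFrame  # one row per differential event
    pearson_r_events: float
    pearson_r_genes: float


def integrate(
    events: Sequence[DifferentialIREvent],
    expression: pd.DataFrame,
    intron_lengths: Mapping[str, int] | None = None,
    panels: Mapping[str, Iterable[str]] | None = None,
) -> IntegrationResult:
    """Join per-intron delta-IR to per-gene expression log2FC.

    The event-level Pearson correlation uses every joined event; the
    gene-level variant uses length-weighted per-gene mean delta-IR.  Genes
    with a zero value on either axis are left unclassified.  ``panels``
    optionally labels genes by reactivity panel membership (pan/A1/A2).
    """
    lfc = expression.set_index("gene_id")["log2fc"]
    rows = []
    for event in events:
        if event.gene_id not in lfc.index:
            continue
        length = (
            intron_lengths.get(event.intron_id, 1)
            if intron_lengths is not None
            else 1
        )
        rows.append(
            {
                "intron_id": event.intron_id,
                "gene_id": event.gene_id,
                "delta_ir": event.delta_ir,
                "log2fc": float(lfc[event.gene_id]),
                "intron_length": length,
                "significant": event.significant,
            }
        )
    per_event = pd.DataFrame(rows)
    if per_event.empty:
        raise ValueError("no events join the expression table")

    gene_rows = []
    for gene_id, group in per_event.groupby("gene_id"):
        mean_delta = gene_mean_delta_ir(
            group["delta_ir"].to_numpy(), group["intron_length"].to_numpy()
        )
        gene_lfc = float(group["log2fc"].iloc[0])
        panel = "none"
        if panels:
            for name, members in panels.items():
                if gene_id in set(members):
                    panel = name
                    break
        gene_rows.append(
            {
                "gene_id": gene_id,
                "mean_delta_ir": mean_delta,
                "log2fc": gene_lfc,
                "n_events": len(group),
                "quadrant": _quadrant(mean_delta, gene_lfc),
                "panel": panel,
            }
        )
    records = pd.DataFrame(gene_rows)

    def _pearson(x: np.ndarray, y: np.ndarray) -> float:
        if x.size < 3:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    r_events = _pearson(
        per_event["delta_ir"].to_numpy(), per_event["log2fc"].to_numpy()
    )
    r_genes = _pearson(
        records["mean_delta_ir"].to_numpy(), records["log2fc"].to_numpy()
    )
    return IntegrationResult(records, per_event, r_events, r_genes)


# ---------------------------------------------------------------------------
# overlap tests
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    k: int
    n1: int
    n2: int
    background: int
    odds_ratio: float
    p_value: float
    method: str = "hypergeometric"


def overlap_test(k: int, n1: int, n2: int, background: int) -> OverlapResult:
    """One-sided hypergeometric upper-tail test of a k-gene overlap between
    sets of sizes n1 and n2 drawn from ``background`` genes (equivalent to
    Fisher's exact test on the 2x2 table)."""
    if not (0 <= k <= min(n1, n2) <= background) or max(n1, n2) > background:
        raise ValueError("infeasible overlap counts")
    if k < n1 + n2 - background:
        raise ValueError("overlap smaller than forced minimum")
    p = float(stats.hypergeom.sf(k - 1, background, n1, n2))
    a, b = k, n1 - k
    c, d = n2 - k, background - n1 - n2 + k
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return OverlapResult(k, n1, n2, background, odds, min(p, 1.0))


def threeway_overlap_test(
    set_sizes: Sequence[int], triple_overlap: int, background: int
) -> tuple[float, float, str]:
    """Test the observed triple overlap against its expectation under
    independence, N * prod(n_i / N).

    Returns (statistic, p, method).  Uses a continuity-corrected 1-df
    chi-squared goodness of fit; when the expectation is below 1 an exact
    Poisson upper tail is substituted (method flags which branch ran).
    """
    if len(set_sizes) != 3:
        raise ValueError("three set sizes required")
    if any(n < 0 or n > background for n in set_sizes) or triple_overlap < 0:
        raise ValueError("infeasible counts")
    expected = background * math.prod(n / background for n in set_sizes)
    if expected < 1.0:
        p = float(stats.poisson.sf(triple_overlap - 1, expected))
        return float(triple_overlap), min(p, 1.0), "poisson-exact"
    corrected = max(abs(triple_overlap - expected) - 0.5, 0.0)
    statistic = corrected**2 / expected
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, "chi-squared"


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    exact: bool
    leading_edge: list[str]


def _enrichment_score(
    scores: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score over a descending ranking.

    Returns (ES, index of the extremum).  Hits advance by |score|^weight
    (normalized), misses retreat by 1/(N - k).
    """
    n = scores.size
    n_hits = int(in_set.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    hit_weights = np.abs(scores) ** weight
    hit_total = hit_weights[in_set].sum()
    if hit_total == 0:  # degenerate all-zero scores: unweighted steps
        steps_hit = np.where(in_set, 1.0 / n_hits, 0.0)
    else:
        steps_hit = np.where(in_set, hit_weights / hit_total, 0.0)
    steps_miss = np.where(~in_set, 1.0 / (n - n_hits), 0.0)
    running = np.cumsum(steps_hit - steps_miss)
    extremum = int(np.argmax(np.abs(running)))
    return float(running[extremum]), extremum


def gsea_preranked(
    scores: pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    set_name: str = "gene_set",
) -> GSEAResult:
    """Preranked GSEA of one gene set against gene-level scores.

    Genes are ranked by score descending; the null is gene-set permutation
    (random same-size subsets of the ranked universe).  When the number of
    distinct subsets is at most ``n_perm`` the null is enumerated
    exhaustively, making the permutation p exact.  NES divides ES by the
    mean |ES| of same-sign permutations; p carries the +1 correction.
    Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranked = scores.sort_values(ascending=False)
    universe = list(ranked.index)
    members = set(gene_set) & set(universe)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    values = ranked.to_numpy(dtype=float)
    in_set = np.array([g in members for g in universe])
    es, extremum = _enrichment_score(values, in_set, weight)

    k = len(members)
    n = len(universe)
    exact = math.comb(n, k) <= n_perm
    perm_es = []
    if exact:
        for combo in itertools.combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perm_es.append(_enrichment_score(values, mask, weight)[0])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            perm_es.append(_enrichment_score(values, mask, weight)[0])
    perm_es = np.asarray(perm_es)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size:
        nes = es / np.abs(same_sign).mean()
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + same_sign.size)
    else:
        nes, p = float("nan"), 1.0 / (1 + len(perm_es))

    if es >= 0:
        leading = [g for g, hit in zip(universe[: extremum + 1], in_set) if hit]
    else:
        leading = [
            g
            for g, hit in zip(universe[extremum:], in_set[extremum:])
            if hit
        ]
    return GSEAResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        p_value=float(p),
        n_perm=len(perm_es),
        exact=exact,
        leading_edge=leading,
    )


# ---------------------------------------------------------------------------
# hypergeometric set enrichment over a GMT collection
# ---------------------------------------------------------------------------


def set_enrichment(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    background: Iterable[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set,
    BH-adjusted across the collection; background must contain the query."""
    from statsmodels.stats.multitest import multipletests

    background = set(background)
    query = set(query) & background
    if not query:
        return pd.DataFrame(
            columns=["set_name", "k", "set_size", "query_size", "p_value",
                     "p_adjusted", "significant"]
        )
    rows = []
    for name, members in collection.items():
        members = set(members) & background
        if not members:
            continue
        k = len(query & members)
        result = overlap_test(k, len(query), len(members), len(background))
        rows.append(
            {
                "set_name": name,
                "k": k,
                "set_size": len(members),
                "query_size": len(query),
                "p_value": result.p_value,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_adjusted"] < fdr_threshold
    return table.sort_values("p_value").reset_index(drop=True)


def grouped_lfc_comparison(
    lfc_a: Sequence[float], lfc_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-sum test between two log-fold-change vectors (used for
    NMD-biotype versus protein-coding transcript comparisons and for IR-up
    versus IR-down comparisons)."""
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 values")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
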