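"""Gene-set statistics: hypergeometric overrepresentation with
Benjamini-Hochberg FDR control, and a weighted Kolmogorov-Smirnov
(GSEA-style) running-sum score with a gene-label permutation null.

These statistics are implemented here directly (log-space hypergeometric
tail, step-up BH, explicit running sum) so that every numerical choice —
tail convention, tie handling, permutation scheme, normalisation — is
visible and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# Hypergeometric upper tail and BH FDR
# ---------------------------------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws).

    Computed by log-space summation of point masses for numerical stability;
    k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"impossible configuration k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    log_denom = _log_choose(N, n)
    logs = [
        _log_choose(K, i) + _log_choose(N - K, n - i) - log_denom
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ]
    if not logs:
        return 0.0
    m = max(logs)
    return min(1.0, math.exp(m) * sum(math.exp(x - m) for x in logs))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-stable.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values, mapped
    back to the input order and clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overrepresentation of one gene set in a query."""

    set_name: str
    k: int      # hits in query
    K: int      # set size within universe
    n: int      # query size
    N: int      # universe size
    p: float
    q: float
    enriched: bool


def ora(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.01,
) -> list[EnrichmentResult]:
    """Overrepresentation of each collection set in the query, BH-adjusted.

    Query genes outside the universe are dropped (count logged via return of
    results only); collection sets are intersected with the universe and
    empty intersections skipped. enriched means q < fdr_threshold (strict).
    """
    if not universe:
        raise ValueError("universe is empty")
    q_in = set(query) & set(universe)
    if not q_in:
        raise ValueError("query is empty after intersecting with universe")
    N, n = len(universe), len(q_in)
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        if not members:
            continue
        K = len(members)
        k = len(members & q_in)
        rows.append((name, k, K, hypergeom_upper_tail(k, K, n, N)))
    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(name, k, K, n, N, p, float(qv), bool(qv < fdr_threshold))
        for (name, k, K, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


# ---------------------------------------------------------------------------
# GSEA running sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float | None
    p_perm: float | None
    n_perm: int
    seed: int | None
    profile: np.ndarray  # running statistic per rank


def _running_profile(scores: np.ndarray, is_hit: np.ndarray, w: float) -> np.ndarray:
    nh = int(is_hit.sum())
    n = scores.size
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit some but not all ranked genes")
    weights = np.abs(scores) ** w
    hit_total = weights[is_hit].sum()
    step = np.where(
        is_hit,
        weights / hit_total if hit_total > 0 else 1.0 / nh,
        -1.0 / (n - nh),
    )
    if hit_total == 0:
        # all hit weights zero (e.g. w>0 with zero scores): uniform hit increments
        step = np.where(is_hit, 1.0 / nh, -1.0 / (n - nh))
    return np.cumsum(step)


def _es_from_profile(profile: np.ndarray) -> float:
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i])


def gsea_es(
    ranked_genes: list[str],
    scores,
    gene_set: set[str],
    weight_exponent: float = 1.0,
    set_name: str = "set",
) -> GseaResult:
    """Classic weighted KS enrichment score of a gene set in a ranked list.

    ranked_genes are ordered best-first with their ranking scores; hits
    advance the running sum by |score|^w normalised over hit weights, misses
    retreat it by 1/(N - Nh); ES is the signed extremum of the profile.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(ranked_genes):
        raise ValueError("ranked_genes and scores differ in length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    is_hit = np.fromiter((g in gene_set for g in ranked_genes), bool, len(ranked_genes))
    profile = _running_profile(scores, is_hit, weight_exponent)
    return GseaResult(set_name, _es_from_profile(profile), None, None, 0, None, profile)


def gsea_permutation(
    ranked_genes: list[str],
    scores,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    set_name: str = "set",
) -> GseaResult:
    """Gene-label permutation test of the enrichment score.

    The hit labels are re-drawn uniformly over rank positions n_perm times;
    p_perm = (1 + #{|es_perm| >= |es_obs|, same sign}) / (1 + #same-sign
    permutations), and NES = es / mean(|es_perm| of the same sign). With no
    same-sign permutations NES is reported as None.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = gsea_es(ranked_genes, scores, gene_set, weight_exponent, set_name)
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    nh = sum(1 for g in ranked_genes if g in gene_set)
    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    hit_mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        hit_mask[:] = False
        hit_mask[rng.choice(n, size=nh, replace=False)] = True
        es_perm[i] = _es_from_profile(_running_profile(scores, hit_mask, weight_exponent))
    same_sign = es_perm * obs.es > 0 if obs.es != 0 else np.ones(n_perm, bool)
    n_same = int(same_sign.sum())
    n_extreme = int(np.sum(np.abs(es_perm[same_sign]) >= abs(obs.es)))
    p_perm = (1 + n_extreme) / (1 + n_same)
    if n_same > 0:
        nes = obs.es / float(np.mean(np.abs(es_perm[same_sign])))
    else:
        nes = None
    return GseaResult(set_name, obs.es, nes, p_perm, n_perm, seed, obs.profile)
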