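"""Fold-change DE calling, condition-pattern cluster assignment of upregulated
genes, and the fraction-of-DE-genes-bound statistic.

Clusters follow a fixed boolean rule over the three conditions
(HIF1 overexpression, HIF2 overexpression, hypoxia): genes upregulated only
under hypoxia form cluster 1 (hypoxia-driven, HIF-independent), only by HIF1
cluster 2, by both HIFs but not hypoxia cluster 3, only by HIF2 cluster 4,
and everything upregulated in all or in mixed HIF+hypoxia patterns cluster 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .intervals_io import ExpressionRecord
from .peak_annotation import GeneBindingMap


@dataclass(frozen=True)
class DeParams:
    """Linear fold-change threshold for calling differential expression."""

    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")


@dataclass(frozen=True)
class DeCallSet:
    """Up/down gene sets for one condition at a fold threshold (strict)."""

    condition: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        assert not (self.up & self.down)


@dataclass(frozen=True)
class FractionBoundResult:
    """How many DE genes carry a promoter peak of the factor."""

    n_bound: int
    n_total: int
    percent: float          # one decimal, round half-up
    percent_int: int        # integer form, round half-up


# pattern (up in HIF1-OE, up in HIF2-OE, up in hypoxia) -> cluster
CLUSTER_RULE: dict[tuple[bool, bool, bool], int | str] = {
    (False, False, True): 1,
    (True, False, False): 2,
    (True, True, False): 3,
    (False, True, False): 4,
    (True, True, True): 5,
    (True, False, True): 5,
    (False, True, True): 5,
    (False, False, False): "unassigned",
}


@dataclass(frozen=True)
class ClusterAssignment:
    gene_id: str
    cluster: int | str
    pattern: tuple[bool, bool, bool]


def call_de(
    records: list[ExpressionRecord],
    condition: str,
    params: DeParams | None = None,
) -> DeCallSet:
    """Call up (fold > threshold) and down (fold < 1/threshold) genes, strict
    inequalities, for one condition."""
    params = params or DeParams()
    rows = [r for r in records if r.condition == condition]
    if not rows:
        raise ValueError(f"no expression records for condition {condition!r}")
    thr = params.fold_threshold
    up = frozenset(r.gene_id for r in rows if r.fold_change > thr)
    down = frozenset(r.gene_id for r in rows if r.fold_change < 1.0 / thr)
    return DeCallSet(condition, up, down)


def assign_clusters(
    de_hif1: DeCallSet, de_hif2: DeCallSet, de_hypoxia: DeCallSet,
    gene_universe: set[str] | None = None,
) -> list[ClusterAssignment]:
    """Assign every gene to a cluster by its (HIF1, HIF2, hypoxia) up-pattern."""
    universe = gene_universe or (set(de_hif1.up) | set(de_hif2.up) | set(de_hypoxia.up))
    out = []
    for gene in sorted(universe):
        pattern = (gene in de_hif1.up, gene in de_hif2.up, gene in de_hypoxia.up)
        out.append(ClusterAssignment(gene, CLUSTER_RULE[pattern], pattern))
    return out


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fraction_bound(de_genes: set[str], bound: GeneBindingMap | set[str]) -> FractionBoundResult:
    """Fraction of a DE gene set whose promoters carry a binding peak.

    Reports the percentage both to one decimal and as an integer (both
    rounded half-up), e.g. 442 of 1139 -> 38.8% / 39%.
    """
    if not de_genes:
        raise ValueError("fraction_bound of an empty DE gene set is undefined")
    bound_set = bound.gene_set() if isinstance(bound, GeneBindingMap) else set(bound)
    n_bound = len(set(de_genes) & bound_set)
    n_total = len(de_genes)
    pct = 100.0 * n_bound / n_total
    return FractionBoundResult(
        n_bound=n_bound,
        n_total=n_total,
        percent=_round_half_up(pct, 1),
        percent_int=int(_round_half_up(pct, 0)),
    )
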