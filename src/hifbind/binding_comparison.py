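"""Two-factor peak comparison: Venn overlap counts, differential binding by
pseudocounted height ratio, and top-N strongest-bound gene ranking."""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .intervals_io import Peak
from .peak_annotation import GeneBindingMap


@dataclass(frozen=True)
class VennCounts:
    """Peak-level overlap counts from both factors' perspectives.

    shared_a counts A peaks overlapping >= 1 B peak (each A peak once however
    many B peaks it touches); shared_b symmetrically. The two shared counts
    can differ, which a two-circle Venn diagram hides.
    """

    a_only: int
    b_only: int
    shared_a: int
    shared_b: int
    total_a: int
    total_b: int

    def __post_init__(self) -> None:
        assert self.a_only + self.shared_a == self.total_a
        assert self.b_only + self.shared_b == self.total_b

    def as_dict(self) -> dict[str, int]:
        return {
            "a_only": self.a_only,
            "b_only": self.b_only,
            "shared_a": self.shared_a,
            "shared_b": self.shared_b,
            "total_a": self.total_a,
            "total_b": self.total_b,
        }


@dataclass(frozen=True)
class DifferentialBindingResult:
    """Partition of the bound-gene union into stronger-A / stronger-B / comparable."""

    stronger_a: frozenset[str]
    stronger_b: frozenset[str]
    comparable: frozenset[str]
    fold: float
    pseudocount: float


def peak_overlap_venn(
    peaks_a: list[Peak], peaks_b: list[Peak], min_overlap_bp: int = 1
) -> VennCounts:
    """Count peaks of each factor that overlap (>= min_overlap_bp shared bases)
    at least one peak of the other factor."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not peaks_a or not peaks_b:
        raise ValueError("both peak sets must be nonempty")

    def count_shared(query: list[Peak], subject: list[Peak]) -> int:
        trees: dict[str, IntervalTree] = {}
        for p in subject:
            trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end
            )
        shared = 0
        for p in query:
            tree = trees.get(p.interval.chrom)
            if tree is None:
                continue
            if any(
                min(p.interval.end, iv.end) - max(p.interval.start, iv.begin)
                >= min_overlap_bp
                for iv in tree.overlap(p.interval.start, p.interval.end)
            ):
                shared += 1
        return shared

    shared_a = count_shared(peaks_a, peaks_b)
    shared_b = count_shared(peaks_b, peaks_a)
    return VennCounts(
        a_only=len(peaks_a) - shared_a,
        b_only=len(peaks_b) - shared_b,
        shared_a=shared_a,
        shared_b=shared_b,
        total_a=len(peaks_a),
        total_b=len(peaks_b),
    )


def differential_binding(
    map_a: GeneBindingMap,
    map_b: GeneBindingMap,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> DifferentialBindingResult:
    """Partition bound genes by the pseudocounted best-height ratio.

    For each gene in either map, r = (h_a + pc) / (h_b + pc) with absent
    heights treated as 0; r >= fold -> stronger_a, r <= 1/fold -> stronger_b,
    else comparable.
    """
    if not fold > 1:
        raise ValueError("fold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    stronger_a, stronger_b, comparable = set(), set(), set()
    for gene in map_a.gene_set() | map_b.gene_set():
        ha = map_a.best_height.get(gene, 0.0)
        hb = map_b.best_height.get(gene, 0.0)
        num, den = ha + pseudocount, hb + pseudocount
        if den == 0:
            r = float("inf") if num > 0 else 1.0
        else:
            r = num / den
        if r >= fold:
            stronger_a.add(gene)
        elif r <= 1.0 / fold:
            stronger_b.add(gene)
        else:
            comparable.add(gene)
    return DifferentialBindingResult(
        frozenset(stronger_a), frozenset(stronger_b), frozenset(comparable),
        fold, pseudocount,
    )


def top_n_bound(gmap: GeneBindingMap, n: int = 200) -> list[str]:
    """First n genes sorted by (-best height, gene_id); ties break lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return gmap.genes()[:n]
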