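"""Assignment of ChIP-seq peaks to promoter windows around gene TSSs.

The promoter window is -5 kb to +1 kb around the TSS in transcription
orientation. A peak is anchored at its summit (midpoint fallback) and
assigned to every gene whose window contains the anchor; an any-overlap
mode is available for comparison. Fractions of TSS-proximal and
lncRNA-proximal peaks, and the gene-level best-height binding map, are
derived from the assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .intervals_io import Peak, TssRecord


@dataclass(frozen=True)
class AnnotationParams:
    """Promoter-window geometry and peak anchoring mode.

    window_upstream/window_downstream are bases 5' and 3' of the TSS in gene
    orientation (defaults 5000 and 1000). anchor is "summit" (midpoint when
    no summit is recorded) or "midpoint"; mode "anchor" assigns by anchor
    containment, "overlap" by any basepair overlap with the window.
    """

    window_upstream: int = 5000
    window_downstream: int = 1000
    anchor: str = "summit"
    mode: str = "anchor"

    def __post_init__(self) -> None:
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ValueError("window sizes must be >= 0")
        if self.window_upstream == 0 and self.window_downstream == 0:
            raise ValueError("window cannot be empty on both sides")
        if self.anchor not in ("summit", "midpoint"):
            raise ValueError(f"unknown anchor mode {self.anchor!r}")
        if self.mode not in ("anchor", "overlap"):
            raise ValueError(f"unknown assignment mode {self.mode!r}")


@dataclass(frozen=True)
class PeakAssignment:
    """One peak assigned to one gene's promoter window.

    distance is the signed offset from TSS to the peak anchor in
    transcription orientation (negative = upstream of the gene).
    """

    peak: str
    gene_id: str
    distance: int
    biotype: str = "coding"


@dataclass
class GeneBindingMap:
    """gene_id -> best (maximum) assigned peak height plus the peak names."""

    best_height: dict[str, float] = field(default_factory=dict)
    peaks: dict[str, list[str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        """Gene ids ordered by (-best height, gene_id)."""
        return sorted(self.best_height, key=lambda g: (-self.best_height[g], g))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.best_height

    def __len__(self) -> int:
        return len(self.best_height)

    def gene_set(self) -> set[str]:
        return set(self.best_height)


def _window(rec: TssRecord, params: AnnotationParams) -> tuple[int, int]:
    """Half-open genomic window containing valid anchor positions.

    + strand: [tss - up, tss + down); - strand reflected: the anchor positions
    with signed distance in [-up, down) are (tss - down, tss + up], i.e. the
    half-open [tss - down + 1, tss + up + 1).
    """
    if rec.strand == "+":
        return rec.tss - params.window_upstream, rec.tss + params.window_downstream
    return rec.tss - params.window_downstream + 1, rec.tss + params.window_upstream + 1


def _anchor(peak: Peak, params: AnnotationParams) -> int:
    if params.anchor == "summit":
        return peak.anchor
    return (peak.interval.start + peak.interval.end) // 2


def assign_peaks_to_tss(
    peaks: list[Peak],
    tss_records: list[TssRecord],
    params: AnnotationParams | None = None,
) -> list[PeakAssignment]:
    """Assign each peak to every gene whose promoter window contains it.

    One peak may yield multiple assignments (overlapping windows, multi-TSS
    genes). Peaks on chromosomes absent from the TSS table simply yield no
    assignments.
    """
    params = params or AnnotationParams()
    if not tss_records:
        raise ValueError("TSS table is empty")
    trees: dict[str, IntervalTree] = {}
    for rec in tss_records:
        lo, hi = _window(rec, params)
        if hi <= lo:
            continue
        trees.setdefault(rec.chrom, IntervalTree()).addi(lo, hi, rec)

    out: list[PeakAssignment] = []
    for peak in peaks:
        tree = trees.get(peak.interval.chrom)
        if tree is None:
            continue
        if params.mode == "anchor":
            pos = _anchor(peak, params)
            hits = tree.at(pos)
        else:
            pos = _anchor(peak, params)
            hits = tree.overlap(peak.interval.start, peak.interval.end)
        for iv in hits:
            rec: TssRecord = iv.data
            dist = pos - rec.tss if rec.strand == "+" else rec.tss - pos
            out.append(PeakAssignment(peak.name, rec.gene_id, dist, rec.biotype))
    return out


@dataclass(frozen=True)
class ProximalFraction:
    """Exact count ratio of TSS-proximal peaks with its float value."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def proximal_fraction(
    peaks: list[Peak],
    assignments: list[PeakAssignment],
    biotype_filter: str = "any",
) -> tuple[float, ProximalFraction]:
    """Fraction of peaks with >= 1 assignment to a TSS of the given biotype.

    Returns the float fraction together with the exact unreduced
    numerator/denominator. biotype_filter is "any", "coding" or "lncRNA".
    """
    if not peaks:
        raise ValueError("proximal_fraction of an empty peak set is undefined")
    if biotype_filter not in ("any", "coding", "lncRNA"):
        raise ValueError(f"unknown biotype filter {biotype_filter!r}")
    hit = {
        a.peak
        for a in assignments
        if biotype_filter == "any" or a.biotype == biotype_filter
    }
    n_hit = sum(1 for p in peaks if p.name in hit)
    ratio = ProximalFraction(n_hit, len(peaks))
    return ratio.fraction, ratio


def gene_binding_map(assignments: list[PeakAssignment], peaks: list[Peak]) -> GeneBindingMap:
    """Collapse assignments to genes, keeping the maximum assigned peak height."""
    heights = {p.name: p.height for p in peaks}
    gmap = GeneBindingMap()
    for a in assignments:
        if a.peak not in heights:
            raise KeyError(f"assignment references unknown peak {a.peak!r}")
        h = heights[a.peak]
        if a.gene_id not in gmap.best_height or h > gmap.best_height[a.gene_id]:
            gmap.best_height[a.gene_id] = h
        gmap.peaks.setdefault(a.gene_id, []).append(a.peak)
    return gmap


def write_assignments(
    assignments: list[PeakAssignment],
    tss_records: list[TssRecord],
    path,
) -> None:
    """Write the assignment table: peak, gene_id, symbol, distance, biotype."""
    symbols = {r.gene_id: r.symbol for r in tss_records}
    with open(path, "w") as fh:
        fh.write("peak\tgene_id\tsymbol\tdistance\tbiotype\n")
        for a in assignments:
            fh.write(
                f"{a.peak}\t{a.gene_id}\t{symbols.get(a.gene_id, a.gene_id)}"
                f"\t{a.distance}\t{a.biotype}\n"
            )
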