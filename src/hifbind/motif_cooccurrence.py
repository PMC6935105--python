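"""PWM scanning of promoter windows and motif (co-)occurrence enrichment at
bound versus background promoters.

Scanning scores log2-odds of a position probability matrix against a 0-order
background on both strands. A window is a hit when its score reaches a fixed
fraction of the PWM's achievable score range (default 0.8) — a deterministic
threshold rule, simpler than p-value-calibrated scanners and adequate for
presence/absence co-occurrence counting. Windows containing N never score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals_io import TssRecord
from .set_enrichment import EnrichmentResult, bh_fdr, hypergeom_upper_tail

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over ACGT with the pseudocount used to
    build it; ``matrix`` has shape (length, 4) and rows summing to 1."""

    name: str
    matrix: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError(f"PWM {self.name}: matrix must be (L>=4, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.5) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True), pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.pseudocount)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """(L, 5) log2-odds table; column 5 is N, scored -inf."""
        lo = np.log2(np.maximum(self.matrix, 1e-300) / background)
        return np.hstack([lo, np.full((self.length, 1), -np.inf)])


def read_pwms(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Read JASPAR-style 4-row count (or probability) matrices."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float).T
        out.append(PWM.from_counts(rec.name or rec.matrix_id, counts, pseudocount))
    return out


@dataclass(frozen=True)
class MotifHit:
    sequence: str
    motif: str
    offset: int   # 0-based on the scanned (forward) sequence
    strand: str
    score: float  # log2-odds, bits


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    L = logodds.shape[0]
    if codes.size < L:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    return logodds[np.arange(L), wins].sum(axis=1)


def score_range(pwm: PWM, background: np.ndarray) -> tuple[float, float]:
    """(min, max) achievable log2-odds over ACGT windows."""
    lo = pwm.log_odds(background)[:, :4]
    return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())


def scan_pwm(
    sequence: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    threshold_fraction: float = 0.8,
    sequence_name: str = "seq",
) -> list[MotifHit]:
    """Scan one sequence on both strands; return hits at or above the
    range-fraction threshold. A motif longer than the sequence yields no hits."""
    bg = _check_background(background)
    seq = sequence.upper()
    if len(seq) < pwm.length:
        return []
    lo_min, lo_max = score_range(pwm, bg)
    thr = lo_min + threshold_fraction * (lo_max - lo_min)
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(codes, mat.log_odds(bg))
        for off in np.nonzero(scores >= thr)[0]:
            hits.append(MotifHit(sequence_name, pwm.name, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _check_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background must be 4 strictly positive frequencies summing to 1")
    return bg


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """0-order base frequencies over a promoter set (N excluded), with a
    pseudocount so no base has zero mass."""
    counts = np.ones(4)
    for s in sequences.values():
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    return counts / counts.sum()


def promoter_windows_to_sequences(
    tss_records: list[TssRecord],
    genome: dict[str, str],
    up: int = 5000,
    down: int = 1000,
) -> dict[str, str]:
    """Extract strand-aware promoter windows (-up..+down around each TSS) from
    a genome; minus-strand windows are reverse-complemented so position `up`
    is always the TSS. Windows are truncated at contig edges and genes on
    missing chromosomes skipped, both with logged warnings."""
    out: dict[str, str] = {}
    n_trunc = n_missing = 0
    for rec in tss_records:
        contig = genome.get(rec.chrom)
        if contig is None:
            n_missing += 1
            continue
        if rec.strand == "+":
            lo, hi = rec.tss - up, rec.tss + down
        else:
            lo, hi = rec.tss - down + 1, rec.tss + up + 1
        clo, chi = max(0, lo), min(len(contig), hi)
        if (clo, chi) != (lo, hi):
            n_trunc += 1
        if chi <= clo:
            continue
        seq = contig[clo:chi]
        out[rec.gene_id] = seq if rec.strand == "+" else reverse_complement(seq)
    if n_missing:
        log.warning("promoter extraction: %d genes on chromosomes absent from FASTA", n_missing)
    if n_trunc:
        log.warning("promoter extraction: %d windows truncated at contig edges", n_trunc)
    return out


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Boolean promoters x motifs presence table plus the scan parameters."""

    table: pd.DataFrame
    threshold_fraction: float
    background: np.ndarray


def build_occurrence_matrix(
    sequences: dict[str, str],
    pwms: list[PWM],
    background: np.ndarray | None = None,
    threshold_fraction: float = 0.8,
) -> OccurrenceMatrix:
    """Scan every promoter with every PWM; background defaults to the 0-order
    composition of the scanned set itself."""
    bg = estimate_background(sequences) if background is None else _check_background(background)
    names = list(sequences)
    data = np.zeros((len(names), len(pwms)), dtype=bool)
    for j, pwm in enumerate(pwms):
        lo_min, lo_max = score_range(pwm, bg)
        thr = lo_min + threshold_fraction * (lo_max - lo_min)
        fwd = pwm.log_odds(bg)
        rev = pwm.reverse_complement().log_odds(bg)
        for i, name in enumerate(names):
            codes = _encode(sequences[name])
            if codes.size < pwm.length:
                continue
            if np.any(_window_scores(codes, fwd) >= thr) or np.any(
                _window_scores(codes, rev) >= thr
            ):
                data[i, j] = True
    table = pd.DataFrame(data, index=names, columns=[p.name for p in pwms])
    return OccurrenceMatrix(table, threshold_fraction, bg)


@dataclass(frozen=True)
class CoOccurrencePair:
    motif_a: str
    motif_b: str
    n_both: int
    jaccard: float


def motif_enrichment(
    bound: set[str],
    background: set[str],
    occurrence: OccurrenceMatrix,
) -> tuple[list[EnrichmentResult], list[CoOccurrencePair]]:
    """Per-motif hypergeometric enrichment among bound promoters against the
    bound+background universe, BH-adjusted, plus pairwise co-occurrence
    (both motifs present in the same bound promoter) with Jaccard indices."""
    if not background:
        raise ValueError("background promoter set is empty")
    if bound & background:
        raise ValueError("bound and background promoter sets must be disjoint")
    tab = occurrence.table
    bound_idx = [p for p in tab.index if p in bound]
    universe_idx = [p for p in tab.index if p in bound or p in background]
    if not bound_idx:
        raise ValueError("no bound promoters present in the occurrence matrix")
    N, n = len(universe_idx), len(bound_idx)
    sub_u = tab.loc[universe_idx]
    sub_b = tab.loc[bound_idx]
    rows = []
    for motif in tab.columns:
        K = int(sub_u[motif].sum())
        k = int(sub_b[motif].sum())
        p = hypergeom_upper_tail(k, K, n, N) if K > 0 else 1.0
        rows.append((motif, k, K, p))
    qvals = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(motif, k, K, n, N, p, float(q), bool(q < 0.01))
        for (motif, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))

    pairs = []
    for a, b in itertools.combinations(tab.columns, 2):
        va, vb = sub_b[a].to_numpy(), sub_b[b].to_numpy()
        both = int(np.sum(va & vb))
        union = int(np.sum(va | vb))
        pairs.append(CoOccurrencePair(a, b, both, both / union if union else 0.0))
    return results, pairs
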