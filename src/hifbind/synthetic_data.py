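"""Seeded generator of a complete synthetic input bundle with known truth.

The generator emulates the statistical structure the analysis assumes: two
ChIP-seq peak sets with designed TSS-proximal and co-binding fractions and
log-normal heights; an expression table in which promoter binding raises the
probability of >2-fold upregulation; promoter sequences with a planted HIF
motif enriched at bound promoters; and the packaged metabolic pathway
definitions with every glycolysis step given a bound isoform. truth.json
records every planted quantity so each pipeline statistic can be checked
against its designed value.

Genes are laid out on a regular grid with jittered TSSs so that promoter
windows never collide; peak anchors are planted either inside a chosen
promoter window (proximal) or well away from all windows (distal), which
makes the planted proximal/co-binding counts exactly recoverable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import pathway_scoring
from .intervals_io import (
    ExpressionRecord,
    GenomicInterval,
    Peak,
    TssRecord,
    write_expression_table,
    write_fasta,
    write_peaks,
    write_tss_table,
)
from .motif_cooccurrence import read_pwms

TRUTH_VERSION = 1

CONDITIONS = ("HIF1-OE", "HIF2-OE", "hypoxia")


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study; identical config + seed gives
    byte-identical output files."""

    seed: int = 17
    n_chroms: int = 4
    chrom_length: int = 9_000_000
    n_genes: int = 2000
    p_lncRNA: float = 0.14
    n_peaks_a: int = 4000
    n_peaks_b: int = 3000
    p_tss_proximal: float = 0.55
    p_cobound: float = 0.15
    height_lognormal: tuple[float, float] = (2.0, 0.75)
    width_lognormal: tuple[float, float] = (math.log(300.0), 0.35)
    p_up_given_bound: float = 0.5
    p_up_given_unbound: float = 0.05
    p_down: float = 0.08
    fold_lognormal_de: tuple[float, float] = (math.log(4.0), 0.4)
    fold_lognormal_null: tuple[float, float] = (0.0, 0.15)
    motif_planted_rate_bound: float = 0.6
    motif_planted_rate_background: float = 0.1
    n_perm_checks: int = 200
    window_upstream: int = 5000
    window_downstream: int = 1000
    plant_pathway_binding: bool = True
    emit_sequences: bool = True  # genome FASTA + planted motifs are optional

    def __post_init__(self) -> None:
        for name in (
            "p_lncRNA", "p_tss_proximal", "p_cobound", "p_up_given_bound",
            "p_up_given_unbound", "p_down", "motif_planted_rate_bound",
            "motif_planted_rate_background",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_peaks_a", "n_peaks_b"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SynthBundle:
    """Paths of the generated files plus the in-memory truth record."""

    out_dir: Path
    tss: Path
    genome: Path | None
    peaks_a: Path
    peaks_b: Path
    expression: Path
    pathways: dict[str, Path]
    motifs: Path | None
    truth_path: Path
    truth: dict


def _gene_layout(cfg: SynthConfig, rng: np.random.Generator, pathway_symbols: list[str]):
    half = max(cfg.window_upstream, cfg.window_downstream) + 1
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)  # ceil
    spacing = cfg.chrom_length // per_chrom
    jitter_max = 1000
    if spacing < 2 * half + jitter_max + 200:
        raise ValueError(
            "promoter windows would collide: increase chrom_length/n_chroms "
            f"(spacing {spacing} < {2 * half + jitter_max + 200})"
        )
    records: list[TssRecord] = []
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        for slot in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            tss = slot * spacing + half + int(rng.integers(0, jitter_max))
            strand = "+" if rng.random() < 0.5 else "-"
            if gi < len(pathway_symbols):
                sym = pathway_symbols[gi]
                biotype = "coding"
            else:
                sym = f"G{gi:05d}"
                biotype = "lncRNA" if rng.random() < cfg.p_lncRNA else "coding"
            records.append(TssRecord(sym, sym, chrom, strand, tss, biotype))
            gi += 1
    return records


def _window(rec: TssRecord, cfg: SynthConfig) -> tuple[int, int]:
    # anchor-containment window, mirroring the annotation convention
    if rec.strand == "+":
        return rec.tss - cfg.window_upstream, rec.tss + cfg.window_downstream
    return rec.tss - cfg.window_downstream + 1, rec.tss + cfg.window_upstream + 1


def _make_peak(
    name: str, chrom: str, anchor: int, cfg: SynthConfig, rng: np.random.Generator
) -> Peak:
    w = int(np.clip(round(rng.lognormal(*cfg.width_lognormal)), 50, 2000))
    start = max(0, anchor - w // 2)
    end = min(cfg.chrom_length, start + w)
    if anchor >= end:
        start, end = max(0, anchor - w + 1), anchor + 1
    height = float(rng.lognormal(*cfg.height_lognormal))
    return Peak(GenomicInterval(chrom, start, end, "."), name, height, summit=anchor)


def _distal_anchor(
    cfg: SynthConfig,
    rng: np.random.Generator,
    window_bounds: dict[str, np.ndarray],
    extra_blocked: dict[str, np.ndarray] | None = None,
    margin: int = 2500,
) -> tuple[str, int]:
    chroms = sorted(window_bounds)
    for _ in range(10_000):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(margin, cfg.chrom_length - margin))
        bounds = window_bounds[chrom]  # flat sorted [lo1, hi1, lo2, hi2, ...]
        idx = int(np.searchsorted(bounds, pos))
        # inside a window (odd index) or within margin of its edges
        near_lo = idx < bounds.size and bounds[idx] - pos < margin and idx % 2 == 0
        near_hi = idx > 0 and pos - bounds[idx - 1] < margin and idx % 2 == 0
        if idx % 2 == 1 or near_lo or near_hi:
            continue
        if extra_blocked is not None:
            anchors = extra_blocked.get(chrom)
            if anchors is not None and anchors.size:
                j = int(np.searchsorted(anchors, pos))
                near = (j < anchors.size and anchors[j] - pos < margin) or (
                    j > 0 and pos - anchors[j - 1] < margin
                )
                if near:
                    continue
        return chrom, pos
    raise RuntimeError("could not place a distal peak anchor; genome too crowded")


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> SynthBundle:
    """Generate the full input bundle into out_dir and return paths + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # ------------------------------------------------------------------ genes
    pathways = pathway_scoring.load_default_pathways()
    pathway_symbols: list[str] = []
    if cfg.plant_pathway_binding:
        for pw in pathways:
            for step in pw.steps:
                for g in sorted(step.isoforms):
                    if g not in pathway_symbols:
                        pathway_symbols.append(g)
        if len(pathway_symbols) > cfg.n_genes:
            raise ValueError("n_genes too small to host the pathway genes")
    genes = _gene_layout(cfg, rng, pathway_symbols)
    by_id = {g.gene_id: g for g in genes}
    windows = {g.gene_id: (g.chrom, *_window(g, cfg)) for g in genes}
    window_bounds: dict[str, np.ndarray] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        ws = sorted((lo, hi) for c, lo, hi in windows.values() if c == chrom)
        window_bounds[chrom] = np.array([x for w in ws for x in w], dtype=np.int64)

    # ------------------------------------------------------------------ peaks A
    n_prox_a = round(cfg.p_tss_proximal * cfg.n_peaks_a)
    glycolysis = next(p for p in pathways if p.name == "glycolysis")
    forced = sorted(glycolysis.all_genes()) if cfg.plant_pathway_binding else []
    if len(forced) > n_prox_a:
        raise ValueError("p_tss_proximal too small to cover glycolysis genes")
    gene_ids = [g.gene_id for g in genes]
    prox_targets = forced + [
        gene_ids[int(i)]
        for i in rng.integers(0, len(gene_ids), n_prox_a - len(forced))
    ]
    peaks_a: list[Peak] = []
    truth_a = []
    for i, gid in enumerate(prox_targets):
        chrom, lo, hi = windows[gid]
        anchor = int(rng.integers(lo, hi))
        peaks_a.append(_make_peak(f"A_{i:05d}", chrom, anchor, cfg, rng))
        truth_a.append({"peak": f"A_{i:05d}", "proximal": True, "gene": gid})
    for i in range(n_prox_a, cfg.n_peaks_a):
        chrom, anchor = _distal_anchor(cfg, rng, window_bounds)
        peaks_a.append(_make_peak(f"A_{i:05d}", chrom, anchor, cfg, rng))
        truth_a.append({"peak": f"A_{i:05d}", "proximal": False, "gene": None})

    # ------------------------------------------------------------------ peaks B
    n_prox_b = round(cfg.p_tss_proximal * cfg.n_peaks_b)
    n_cob = round(cfg.p_cobound * n_prox_a)
    if n_cob > n_prox_b:
        raise ValueError("p_cobound exceeds B's proximal budget")
    # Plant co-binding window-greedily: whenever a gene window is chosen, every
    # A peak in it receives an overlapping B peak, so no un-planted A peak is
    # left in a window holding B peaks and the planted Venn counts stay exact.
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(prox_targets):
        groups.setdefault(g, []).append(i)
    order = sorted(groups, key=lambda g: (len(groups[g]), g))
    perm = rng.permutation(len(order))
    order = [order[int(i)] for i in np.argsort(perm, kind="stable")]
    order.sort(key=lambda g: len(groups[g]))  # stable: random within same size
    chosen: list[int] = []
    for g in order:
        if len(chosen) + len(groups[g]) <= n_cob:
            chosen.extend(groups[g])
        if len(chosen) == n_cob:
            break
    if len(chosen) < n_cob:
        # only larger windows remain; take a partial one to reach the target
        for g in order:
            if set(groups[g]) & set(chosen):
                continue
            chosen.extend(groups[g][: n_cob - len(chosen)])
            if len(chosen) == n_cob:
                break
    n_cob = len(chosen)
    cob_idx = np.array(sorted(chosen), dtype=np.int64)
    bound_a = {t["gene"] for t in truth_a if t["proximal"]}
    free_genes = [g for g in gene_ids if g not in bound_a]
    if not free_genes and n_prox_b > n_cob:
        raise ValueError("no A-free genes left for B-only proximal peaks")
    peaks_b: list[Peak] = []
    truth_b = []
    for j, ai in enumerate(cob_idx):
        a_peak = peaks_a[int(ai)]
        gid = truth_a[int(ai)]["gene"]
        peaks_b.append(_make_peak(f"B_{j:05d}", a_peak.interval.chrom, a_peak.summit, cfg, rng))
        truth_b.append({"peak": f"B_{j:05d}", "proximal": True, "gene": gid,
                        "cobound_with": a_peak.name})
    for j in range(n_cob, n_prox_b):
        gid = free_genes[int(rng.integers(0, len(free_genes)))]
        chrom, lo, hi = windows[gid]
        anchor = int(rng.integers(lo, hi))
        peaks_b.append(_make_peak(f"B_{j:05d}", chrom, anchor, cfg, rng))
        truth_b.append({"peak": f"B_{j:05d}", "proximal": True, "gene": gid,
                        "cobound_with": None})
    a_anchors = {
        chrom: np.array(sorted(p.summit for p in peaks_a if p.interval.chrom == chrom),
                        dtype=np.int64)
        for chrom in window_bounds
    }
    for j in range(n_prox_b, cfg.n_peaks_b):
        chrom, anchor = _distal_anchor(cfg, rng, window_bounds, extra_blocked=a_anchors)
        peaks_b.append(_make_peak(f"B_{j:05d}", chrom, anchor, cfg, rng))
        truth_b.append({"peak": f"B_{j:05d}", "proximal": False, "gene": None,
                        "cobound_with": None})
    bound_b = {t["gene"] for t in truth_b if t["proximal"]}

    # -------------------------------------------------------------- expression
    drivers = {
        "HIF1-OE": bound_a,
        "HIF2-OE": bound_b,
        "hypoxia": bound_a | bound_b,
    }
    mu_de, sd_de = cfg.fold_lognormal_de
    mu0, sd0 = cfg.fold_lognormal_null
    log2thr = math.log(2.0)
    expr: list[ExpressionRecord] = []
    de_truth: dict[str, dict[str, list[str]]] = {}
    for cond in CONDITIONS:
        up_genes, down_genes = [], []
        for g in gene_ids:
            p_up = cfg.p_up_given_bound if g in drivers[cond] else cfg.p_up_given_unbound
            u = rng.random()
            if u < p_up:
                lf = rng.normal(mu_de, sd_de)
                while lf <= log2thr:
                    lf = rng.normal(mu_de, sd_de)
                fold = math.exp(lf)
                up_genes.append(g)
            elif u < p_up + cfg.p_down * (1 - p_up):
                lf = rng.normal(mu_de, sd_de)
                while lf <= log2thr:
                    lf = rng.normal(mu_de, sd_de)
                fold = math.exp(-lf)
                down_genes.append(g)
            else:
                fold = math.exp(rng.normal(mu0, sd0))
            expr.append(ExpressionRecord(g, cond, fold))
        de_truth[cond] = {"up": up_genes, "down": down_genes}

    # ------------------------------------------------------------------ genome
    planted_motifs: list[dict] = []
    genome_path = motifs_path = None
    if cfg.emit_sequences:
        base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        contigs: dict[str, bytearray] = {}
        for ci in range(cfg.n_chroms):
            codes = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
            contigs[f"chr{ci + 1}"] = bytearray(base_lut[codes].tobytes())

        pwm_src = resources.files("hifbind").joinpath(
            "data/motifs/synthetic_motifs.jaspar"
        )
        motifs_path = out / "motifs.jaspar"
        motifs_path.write_text(pwm_src.read_text())
        hif_pwm = read_pwms(motifs_path)[0]
        consensus = hif_pwm.consensus().encode()
        L = len(consensus)
        bound_any = bound_a | bound_b
        for g in gene_ids:
            rate = (
                cfg.motif_planted_rate_bound
                if g in bound_any
                else cfg.motif_planted_rate_background
            )
            if rng.random() >= rate:
                continue
            chrom, lo, hi = windows[g]
            gpos = int(rng.integers(lo, hi - L))
            contigs[chrom][gpos:gpos + L] = consensus
            rec = by_id[g]
            offset = gpos - lo if rec.strand == "+" else hi - (gpos + L)
            planted_motifs.append(
                {"gene": g, "chrom": chrom, "genomic_pos": gpos,
                 "promoter_offset": offset}
            )

    # ------------------------------------------------------------------ write
    tss_path = out / "tss.tsv"
    write_tss_table(genes, tss_path)
    if cfg.emit_sequences:
        genome_path = out / "genome.fa"
        write_fasta({c: contigs[c].decode() for c in sorted(contigs)}, genome_path)
    pa_path, pb_path = out / "peaks_a.narrowPeak", out / "peaks_b.narrowPeak"
    write_peaks(peaks_a, pa_path)
    write_peaks(peaks_b, pb_path)
    expr_path = out / "expression.tsv"
    write_expression_table(expr, expr_path, wide=True)
    pw_dir = out / "pathways"
    pw_dir.mkdir(exist_ok=True)
    pw_paths: dict[str, Path] = {}
    for pw in pathways:
        p = pw_dir / f"{pw.name}.tsv"
        pathway_scoring.write_pathway(pw, p)
        pw_paths[pw.name] = p

    truth = {
        "version": TRUTH_VERSION,
        # JSON-normalised (tuples -> lists) so in-memory truth == on-disk truth
        "config": json.loads(json.dumps(dataclasses.asdict(cfg))),
        "n_prox_a": n_prox_a,
        "n_prox_b": n_prox_b,
        "n_cobound": n_cob,
        "peaks_a": truth_a,
        "peaks_b": truth_b,
        "bound_a": sorted(bound_a),
        "bound_b": sorted(bound_b),
        "de": de_truth,
        "planted_motifs": planted_motifs,
        "glycolysis_fully_bound_by_a": bool(cfg.plant_pathway_binding),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return SynthBundle(
        out_dir=out, tss=tss_path, genome=genome_path, peaks_a=pa_path,
        peaks_b=pb_path, expression=expr_path, pathways=pw_paths,
        motifs=motifs_path, truth_path=truth_path, truth=truth,
    )


def truth_summary(truth: dict) -> dict[str, dict]:
    """Designed value and 3-SD sampling tolerance for each recoverable statistic."""
    if truth.get("version") != TRUTH_VERSION:
        raise ValueError(f"truth version mismatch: {truth.get('version')}")
    cfg = truth["config"]
    n_a, n_b = cfg["n_peaks_a"], cfg["n_peaks_b"]
    p = cfg["p_tss_proximal"]
    out: dict[str, dict] = {
        "proximal_fraction_a": {
            "planted": truth["n_prox_a"] / n_a,
            "tolerance": 3 * math.sqrt(p * (1 - p) / n_a),
        },
        "proximal_fraction_b": {
            "planted": truth["n_prox_b"] / n_b,
            "tolerance": 3 * math.sqrt(p * (1 - p) / n_b),
        },
        "cobound_count": {
            "planted": truth["n_cobound"],
            "tolerance": 3 * math.sqrt(
                cfg["p_cobound"] * (1 - cfg["p_cobound"]) * truth["n_prox_a"]
            ),
        },
    }
    n_genes = cfg["n_genes"]
    pub, puu = cfg["p_up_given_bound"], cfg["p_up_given_unbound"]
    for cond, bound_key in (("HIF1-OE", "bound_a"), ("HIF2-OE", "bound_b")):
        nb = len(truth[bound_key])
        e_up = nb * pub + (n_genes - nb) * puu
        p_exp = nb * pub / e_up if e_up > 0 else 0.0
        out[f"fraction_bound_up_{cond}"] = {
            "planted": 100.0 * p_exp,
            "tolerance": 100.0 * 3 * math.sqrt(p_exp * (1 - p_exp) / e_up),
        }
    if truth.get("glycolysis_fully_bound_by_a"):
        out["glycolysis_coverage_a"] = {"planted": 100.0, "tolerance": 0.0}
    out["gsea_es_sign"] = {"planted": 1.0, "tolerance": 0.0}
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
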