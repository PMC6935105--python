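"""End-to-end orchestration: peak annotation, two-factor comparison,
expression integration, pathway coverage, enrichment and motif stages,
assembled into one reproducible report keyed by config + seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .binding_comparison import differential_binding, peak_overlap_venn, top_n_bound
from .expression_integration import (
    DeParams,
    assign_clusters,
    call_de,
    fraction_bound,
)
from .intervals_io import (
    read_expression_table,
    read_fasta,
    read_gmt,
    read_peaks,
    read_tss_table,
)
from .motif_cooccurrence import (
    build_occurrence_matrix,
    motif_enrichment,
    promoter_windows_to_sequences,
    read_pwms,
)
from .pathway_scoring import load_default_pathways, pathway_coverage, read_pathway
from .peak_annotation import (
    AnnotationParams,
    assign_peaks_to_tss,
    gene_binding_map,
    proximal_fraction,
)
from .set_enrichment import gsea_permutation, ora

log = logging.getLogger(__name__)

ALL_STAGES = (
    "annotate", "venn", "diff", "de", "fractions", "coverage", "ora", "gsea", "motifs",
)

# factor -> overexpression condition it drives
FACTOR_CONDITIONS = {"a": "HIF1-OE", "b": "HIF2-OE"}


@dataclass(frozen=True)
class AnalysisConfig:
    """All numeric thresholds of the analysis with their defaults.

    window and fold defaults follow the study design (-5 kb/+1 kb promoter
    window, 2-fold expression threshold, top 200 bound loci, ORA FDR 0.01);
    diff_fold, pseudocount, coverage_mode, motif_threshold and n_perm are
    package defaults (not from the study).
    """

    window_upstream: int = 5000
    window_downstream: int = 1000
    anchor: str = "summit"
    de_fold: float = 2.0
    top_n: int = 200
    ora_fdr: float = 0.01
    diff_fold: float = 2.0
    pseudocount: float = 1.0
    coverage_mode: str = "all_steps"
    motif_threshold: float = 0.8
    n_perm: int = 1000
    seed: int = 17
    peak_format: str = "narrowpeak"

    def __post_init__(self) -> None:
        AnnotationParams(self.window_upstream, self.window_downstream, self.anchor)
        if not self.de_fold > 1:
            raise ValueError("de_fold must be > 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.ora_fdr < 1:
            raise ValueError("ora_fdr must be in (0, 1)")
        if self.coverage_mode not in ("all_steps", "prefix"):
            raise ValueError("coverage_mode must be all_steps or prefix")
        if not 0 < self.motif_threshold <= 1:
            raise ValueError("motif_threshold must be in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.peak_format not in ("narrowpeak", "bed6"):
            raise ValueError("peak_format must be narrowpeak or bed6")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def template(self) -> str:
        lines = ["# hifbind analysis configuration"]
        study = {"window_upstream", "window_downstream", "de_fold", "top_n", "ora_fdr"}
        for f in dataclasses.fields(self):
            tag = "study design" if f.name in study else "default (not from study data)"
            lines.append(f"{f.name}: {getattr(self, f.name)}  # {tag}")
        return "\n".join(lines) + "\n"


def _hash_config(cfg: AnalysisConfig, input_hashes: dict[str, str]) -> str:
    payload = json.dumps(
        {"config": dataclasses.asdict(cfg), "inputs": input_hashes}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(
    config: AnalysisConfig,
    inputs: dict[str, object],
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the requested stages and return the report dictionary.

    inputs: peaks_a, peaks_b, tss, expression (paths); optional: pathways
    (list of paths; packaged defaults when absent), gmt, genome, motifs.
    Stages always recompute their prerequisites, so a stage-subset run agrees
    field-for-field with the full run.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    t0 = time.time()
    input_hashes = {
        k: _file_hash(v)
        for k, v in sorted(inputs.items())
        if isinstance(v, (str, Path)) and Path(v).is_file()
    }
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "input_hashes": input_hashes,
            "hash": _hash_config(config, input_hashes),
        }
    }

    tss = read_tss_table(inputs["tss"])
    peaks_a = read_peaks(inputs["peaks_a"], config.peak_format)
    peaks_b = read_peaks(inputs["peaks_b"], config.peak_format)
    params = AnnotationParams(
        config.window_upstream, config.window_downstream, config.anchor
    )
    assign_a = assign_peaks_to_tss(peaks_a, tss, params)
    assign_b = assign_peaks_to_tss(peaks_b, tss, params)
    map_a = gene_binding_map(assign_a, peaks_a)
    map_b = gene_binding_map(assign_b, peaks_b)
    symbols = {r.gene_id: r.symbol for r in tss}

    if "annotate" in stages:
        prox = {}
        for label, pk, asg in (("a", peaks_a, assign_a), ("b", peaks_b, assign_b)):
            f_any, r_any = proximal_fraction(pk, asg, "any")
            f_lnc, r_lnc = proximal_fraction(pk, asg, "lncRNA")
            prox[label] = {
                "any": f_any, "any_ratio": f"{r_any.numerator}/{r_any.denominator}",
                "lncRNA": f_lnc, "lncRNA_ratio": f"{r_lnc.numerator}/{r_lnc.denominator}",
                "n_bound_genes": len(map_a if label == "a" else map_b),
            }
        report["proximal"] = prox

    if "venn" in stages:
        report["venn"] = peak_overlap_venn(peaks_a, peaks_b).as_dict()

    if "diff" in stages:
        db = differential_binding(map_a, map_b, config.diff_fold, config.pseudocount)
        report["differential_binding"] = {
            "stronger_a": len(db.stronger_a),
            "stronger_b": len(db.stronger_b),
            "comparable": len(db.comparable),
            "fold": db.fold,
            "pseudocount": db.pseudocount,
        }

    needs_de = {"de", "fractions", "gsea"} & set(stages)
    if needs_de:
        expr = read_expression_table(inputs["expression"])
        de_params = DeParams(config.de_fold)
        conditions = sorted({r.condition for r in expr})
        de = {c: call_de(expr, c, de_params) for c in conditions}

    if "de" in stages:
        report["de"] = {
            c: {"n_up": len(d.up), "n_down": len(d.down)} for c, d in de.items()
        }
        if {"HIF1-OE", "HIF2-OE", "hypoxia"} <= set(de):
            clusters = assign_clusters(de["HIF1-OE"], de["HIF2-OE"], de["hypoxia"])
            sizes: dict[str, int] = {}
            for ca in clusters:
                sizes[str(ca.cluster)] = sizes.get(str(ca.cluster), 0) + 1
            report["clusters"] = sizes

    if "fractions" in stages:
        fr: dict = {}
        for label, gmap in (("a", map_a), ("b", map_b)):
            cond = FACTOR_CONDITIONS[label]
            if cond not in de:
                continue
            fr[label] = {}
            for direction, genes in (("up", de[cond].up), ("down", de[cond].down)):
                if not genes:
                    continue
                r = fraction_bound(set(genes), gmap)
                fr[label][direction] = {
                    "n_bound": r.n_bound, "n_total": r.n_total,
                    "percent": r.percent, "percent_int": r.percent_int,
                }
        report["fraction_bound"] = fr

    if "coverage" in stages:
        if inputs.get("pathways"):
            pathways = [read_pathway(p) for p in inputs["pathways"]]
        else:
            pathways = load_default_pathways()
        cov: dict = {}
        for label, gmap in (("a", map_a), ("b", map_b)):
            bound_symbols = {symbols.get(g, g) for g in gmap.gene_set()}
            cov[label] = {}
            for pw in pathways:
                r = pathway_coverage(pw, bound_symbols, config.coverage_mode)
                cov[label][pw.name] = {
                    "percent": r.percent,
                    "covered_steps": r.covered_steps,
                    "total_steps": r.total_steps,
                    "all_consecutive": r.all_consecutive,
                }
        report["coverage"] = cov

    if "ora" in stages:
        if inputs.get("gmt"):
            collection = read_gmt(inputs["gmt"])
        else:
            collection = {
                pw.name: pw.all_genes()
                for pw in (
                    [read_pathway(p) for p in inputs["pathways"]]
                    if inputs.get("pathways") else load_default_pathways()
                )
            }
            collection = {
                name: {g for g, s in symbols.items() if s in genes} or genes
                for name, genes in collection.items()
            }
        universe = {r.gene_id for r in tss}
        query = map_a.gene_set() & map_b.gene_set() & universe
        if query:
            results = ora(query, collection, universe, config.ora_fdr)
            report["ora"] = [
                {"set": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                 "p": r.p, "q": r.q, "enriched": r.enriched}
                for r in results
            ]
        else:
            report["ora"] = []

    if "gsea" in stages:
        gsea_out = []
        for label, gmap in (("a", map_a), ("b", map_b)):
            top = set(top_n_bound(gmap, config.top_n))
            for cond in sorted(de):
                rows = sorted(
                    ((r.gene_id, math.log2(r.fold_change))
                     for r in expr if r.condition == cond),
                    key=lambda t: (-t[1], t[0]),
                )
                genes = [g for g, _ in rows]
                scores = [s for _, s in rows]
                hit = top & set(genes)
                if not hit or len(hit) == len(genes):
                    continue
                res = gsea_permutation(
                    genes, scores, top, config.n_perm, config.seed,
                    set_name=f"top{config.top_n}_bound_{label}",
                )
                gsea_out.append({
                    "factor": label, "condition": cond, "es": res.es,
                    "nes": res.nes, "p_perm": res.p_perm, "n_perm": res.n_perm,
                })
        report["gsea"] = gsea_out

    if "motifs" in stages and inputs.get("genome") and inputs.get("motifs"):
        genome = read_fasta(inputs["genome"])
        pwms = read_pwms(inputs["motifs"])
        promoters = promoter_windows_to_sequences(
            tss, genome, config.window_upstream, config.window_downstream
        )
        occ = build_occurrence_matrix(
            promoters, pwms, threshold_fraction=config.motif_threshold
        )
        bound = (map_a.gene_set() | map_b.gene_set()) & set(promoters)
        background = set(promoters) - bound
        results, pairs = motif_enrichment(bound, background, occ)
        report["motifs"] = {
            "enrichment": [
                {"motif": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                 "p": r.p, "q": r.q, "enriched": r.enriched}
                for r in results
            ],
            "co_occurrence": [
                {"a": p.motif_a, "b": p.motif_b, "n_both": p.n_both,
                 "jaccard": p.jaccard}
                for p in sorted(pairs, key=lambda x: -x.n_both)
            ],
        }

    log.info("pipeline finished in %.1fs (stages: %s)", time.time() - t0, ",".join(stages))
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Atomic JSON report write (tmp file + rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(report, indent=1, sort_keys=True))
    os.replace(tmp, path)
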