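"""Pathway step-coverage: the fraction of ordered enzymatic steps in a
pathway with at least one bound isoform gene.

A pathway is an ordered list of enzymatic steps, each carrying the set of
isoform genes able to catalyse it (e.g. the phosphofructokinase step holds
PFKL, PFKP and PFKM). A step is covered when any isoform is in the bound
set; 100% coverage means every consecutive step of the pathway has a bound
isoform. Packaged definitions for glycolysis, TCA cycle and glutaminolysis
are included; steps completed from standard pathway membership rather than
enumerated by the source screens are flagged curated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class PathwayStep:
    name: str
    isoforms: frozenset[str]
    curated: bool = False

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"step {self.name}: needs >= 1 isoform")


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    steps: tuple[PathwayStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"pathway {self.name}: needs >= 1 step")

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.steps:
            out |= s.isoforms
        return out


@dataclass(frozen=True)
class CoverageResult:
    pathway: str
    covered_steps: int
    total_steps: int
    percent: float
    per_step: tuple[tuple[str, frozenset[str]], ...]  # (step name, bound isoforms)
    all_consecutive: bool


def pathway_coverage(
    pathway: PathwayDefinition,
    bound: set[str],
    mode: str = "all_steps",
) -> CoverageResult:
    """Score how much of a pathway is covered by a bound gene set.

    mode "all_steps" (default): percent = fraction of steps with >= 1 bound
    isoform, anywhere along the pathway. mode "prefix": percent = longest
    covered run of steps from pathway entry. all_consecutive is true iff
    every step is covered (identical under both modes).
    """
    if mode not in ("all_steps", "prefix"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    per_step = tuple(
        (s.name, frozenset(s.isoforms & bound)) for s in pathway.steps
    )
    covered_flags = [bool(hits) for _, hits in per_step]
    if mode == "all_steps":
        covered = sum(covered_flags)
    else:
        covered = 0
        for flag in covered_flags:
            if not flag:
                break
            covered += 1
    total = len(pathway.steps)
    return CoverageResult(
        pathway=pathway.name,
        covered_steps=covered,
        total_steps=total,
        percent=100.0 * covered / total,
        per_step=per_step,
        all_consecutive=all(covered_flags),
    )


# ---------------------------------------------------------------------------
# Text format: line 1 "pathway<TAB>name"; then one line per step:
# "step_name<TAB>isoform1,isoform2[<TAB>curated]". '#' lines are comments.
# ---------------------------------------------------------------------------

def read_pathway(path: str | Path) -> PathwayDefinition:
    name = None
    steps: list[PathwayStep] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if name is None:
                if cols[0] != "pathway" or len(cols) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'pathway<TAB>name' header")
                name = cols[1]
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected step_name<TAB>isoforms")
            isoforms = frozenset(g for g in cols[1].split(",") if g)
            curated = len(cols) > 2 and cols[2].strip().lower() == "curated"
            steps.append(PathwayStep(cols[0], isoforms, curated))
    if name is None:
        raise ValueError(f"{path}: no pathway header found")
    return PathwayDefinition(name, tuple(steps))


def write_pathway(pathway: PathwayDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"pathway\t{pathway.name}\n")
        for s in pathway.steps:
            cols = [s.name, ",".join(sorted(s.isoforms))]
            if s.curated:
                cols.append("curated")
            fh.write("\t".join(cols) + "\n")


_DEFAULT_FILES = ("glycolysis.tsv", "tca.tsv", "glutaminolysis.tsv")


def load_default_pathways() -> list[PathwayDefinition]:
    """Load the packaged glycolysis, TCA-cycle and glutaminolysis definitions."""
    out = []
    base = resources.files("hifbind").joinpath("data/pathways")
    for fname in _DEFAULT_FILES:
        with resources.as_file(base.joinpath(fname)) as p:
            out.append(read_pathway(p))
    return out
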