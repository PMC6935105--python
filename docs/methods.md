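# Methods

`hifbind` re-implements, as a reusable library, the integrative analysis of
HIF1α/HIF2α chromatin binding and hypoxia-driven transcription in leukemic
cells: promoter-window peak annotation, two-factor co-binding, intersection
of binding with fold-change expression calls, metabolic-pathway step
coverage, set enrichment (hypergeometric ORA and a GSEA-style running sum)
and promoter motif co-occurrence. This note records the model behind each
statistic, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Coordinates and promoter windows

All internal coordinates are 0-based half-open (BED convention); GTF input
is converted on ingestion (TSS = start−1 on +, end−1 on −). The promoter
window is −5 kb to +1 kb around the TSS in transcription orientation, the
window used throughout the original screens. A peak is represented by a
single anchor — its summit when the peak file records one, otherwise the
floor midpoint — and is assigned to every gene whose window contains the
anchor. Anchoring gives each peak one position and therefore unambiguous
signed TSS distances; an any-overlap mode (`mode="overlap"`) is available
because the source analysis does not state which rule produced its counts.
For a − strand gene the set of anchor positions with signed distance in
[−up, down) is the half-open genomic interval [tss−down+1, tss+up+1); the
strand-aware window is the field convention even though the −5 kb/+1 kb
phrasing does not state strandedness. Genes with several TSS entries get one
window each; the gene-level binding map collapses duplicates and keeps the
maximum assigned peak height.

## Two-factor comparison

Venn counts are peak-level: `shared_a` is the number of A peaks overlapping
(≥ `min_overlap_bp`, default 1) at least one B peak, however many it
touches. The counts from A's and B's perspectives are both reported because
they can differ — a fact a two-circle diagram hides. Differential binding
uses a pseudocounted best-height ratio r = (h_A + 1)/(h_B + 1) with absent
heights as 0 and a 2-fold default; no replicate structure exists in this
design, so a statistical differential-binding model would be spurious
precision. The ratio rule and its threshold are config surfaces, not an
inference of the original criterion, which is unstated. Top-N ranking sorts
by (−height, gene_id); the lexicographic tie-break is documented rather than
arbitrary.

## Expression integration

Differential expression is a strict linear fold-change call (> 2 up,
< 0.5 down); fold changes are inputs, not computed from raw signal.
Upregulated genes are assigned to clusters by their boolean up-pattern
across (HIF1-OE, HIF2-OE, hypoxia): (0,0,1)→1 (hypoxia-driven,
HIF-independent), (1,0,0)→2, (1,1,0)→3, (0,1,0)→4, and all patterns
combining HIF and hypoxia induction →5. The source figure legend defines
clusters by condition membership, so a deterministic rule table replaces any
clustering algorithm; the two mixed patterns (1,0,1)/(0,1,1) have no legend
entry and are assigned to cluster 5 by explicit choice. Fraction-bound
reports the percentage both to one decimal and as a half-up-rounded integer
(442/1139 → 38.8% and 39%), because the original figures print integers.

## Pathway step coverage

A pathway is an ordered list of enzymatic steps, each holding the isoform
genes able to catalyse it. A step is covered when ≥ 1 isoform is bound;
percent = covered/total steps, and the `all_consecutive` flag is true iff
every step is covered — "at each consecutive step" is read as "every step
along the pathway", which makes 100% coincide exactly with
at-least-one-isoform-per-step. The alternative longest-covered-prefix
reading is available as `coverage_mode="prefix"`. Under the default reading,
percent is invariant to step order and `all_consecutive` depends only on the
covered count; both are documented consequences of the interpretation, not
accidents. Packaged definitions cover glycolysis (15 steps, including
transport, PFKFB regulation, PDK and lactate export), TCA cycle (9 steps)
and glutaminolysis (4 steps). Steps and isoforms not enumerable from the
source text are completed from standard pathway membership and flagged
`curated` in the packaged files; the statistic itself is independent of any
particular curation, and users can substitute their own definition files
(one header line, then `step_name<TAB>isoforms[<TAB>curated]`).

## Set enrichment

The hypergeometric upper tail P[X ≥ k] is computed by log-space summation of
point masses (lgamma-based binomials, log-sum-exp), exact to ~1e−12 against
exhaustive enumeration. Benjamini–Hochberg q-values use the step-up formula
with cumulative minima and are stable under input order. ORA intersects
every collection set with the universe, drops query genes outside it, and
declares enrichment at q < threshold (strict, default 0.01). The universe
defaults to all genes of the TSS table since the original background is
unstated; it is a config surface.

The GSEA score is the classic weighted Kolmogorov–Smirnov running sum: hits
advance by |score|^w normalised over hit weights (w = 1 default), misses
retreat by 1/(N−N_h); ES is the signed extremum of the profile. The null is
a gene-label permutation (hit positions re-drawn uniformly), appropriate
because the ranking has no sample-level replicates to permute;
p = (1 + #{|ES*| ≥ |ES|, same sign})/(1 + #same-sign permutations) and
NES = ES / mean|ES*| over same-sign permutations (reported as undefined if
none exist). Everything is reproducible from the seed. Note the degenerate
singleton-at-last-rank case: the profile descends to −1 before the final
hit, so ES = −1 by the running-sum definition.

## Motif scanning and co-occurrence

PWMs are position probability matrices built from JASPAR-style count
matrices with a 0.5 pseudocount per cell. Scanning scores log2-odds against
a 0-order background on both strands; the default background is estimated
from the scanned promoter set itself (the FIMO-style default), overridable.
A window is a hit when its score reaches
min + 0.8·(max − min) of the PWM's achievable score range — a deterministic
rule, simpler than p-value calibration and adequate for presence/absence
co-occurrence counting; it is a documented departure from p-value-calibrated
scanners, and it makes hit counts threshold-monotone by construction.
Windows containing N never score. Per-motif enrichment at bound vs
background promoters is the same hypergeometric/BH machinery; pairwise
co-occurrence is counted as both-present in the same bound promoter and
summarised with a Jaccard index.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the study's design values: 55% of peaks TSS-proximal (the screens report
50–60%), 15% of factor-A proximal peaks co-bound (581 of 3871 shared is
~15%), 14% lncRNA gene biotype (13–15% lncRNA-proximal peaks), log-normal
peak heights and ~300 bp median widths, and binding-coupled upregulation
P(up | bound) = 0.5 vs P(up | unbound) = 0.05 per condition, which yields
the strong bound-fraction and positive GSEA signal the integration is meant
to detect. Up-gene fold changes are log-normal around 4-fold truncated above
the 2-fold threshold; null genes sit tightly around 1 (σ = 0.15 in log
space) so essentially never cross the threshold by chance; a flat 8%
down-regulation rate exercises the down-direction statistics.

Genes are placed on a per-chromosome grid (default 4 × 9 Mb for 2000 genes)
with jittered TSSs so promoter windows never collide; proximal peak anchors
are drawn inside a chosen window, distal anchors ≥ 2.5 kb away from every
window, and factor-B peaks avoid factor-A neighbourhoods except where
co-binding is planted. Co-binding is planted window-greedily — whole gene
windows at a time — so no un-planted A peak shares a window with a planted B
peak. These margins make the planted proximal fraction and co-binding count
exactly recoverable, which is deliberate: the generator tests the pipeline's
bookkeeping at designed values, while sampling noise still enters through
which genes are bound, DE calls and motif planting. Every glycolysis gene
receives a factor-A promoter peak (`plant_pathway_binding`), pinning the
expected glycolysis coverage at 100%. A 14-bp synthetic HIF motif consensus
is written into promoters at rate 0.6 (bound genes) vs 0.1 (background);
the packaged motif collection (HIF/NRF1/SP1/ELK1-like, all synthetic
matrices) uses 14-bp sharp columns because at the fixed 0.8 range threshold
shorter matrices accumulate chance hits over 6 kb windows and saturate the
presence table. `truth.json` records every planted quantity;
`truth_summary` turns it into designed values with 3-SD binomial
tolerances.

What the generator does **not** emulate: realistic genome composition or
peak-caller artefacts, probe-level expression noise, overlapping promoter
windows, enhancer-distance effects, and the original data's absolute peak
counts. Passing recovery tests therefore demonstrates that the statistics
are computed correctly under the assumed structure — not that the original
accession's numbers (3871 proximal peaks, 581 shared, the 100/77/23/8%
coverage pie) would be reproduced; those require the deposited ChIP-seq data
and peak calls.

## Problem sizes and numerics

The default test suite runs a reduced study (400 genes, 800/600 peaks,
2 × 3 Mb genome) for speed, and the parameter-recovery checks run 20 seeds
at the full 2000-gene design without sequence output; the acceptance script
runs one full bundle including the 36 Mb genome and motif scan. Rounding of
percentages is decimal half-up. Degenerate inputs are errors, not silent
results: empty peak sets, empty DE sets, gene sets disjoint from or equal to
a ranking, overlapping bound/background promoter groups, impossible
hypergeometric configurations. Reports are written atomically and are
byte-identical across reruns at a fixed config + seed.

## Known limitations

* Fold-change inputs only; no variance-aware DE model, by design.
* The motif threshold rule is not calibrated to a false-positive rate; use
  the occurrence matrix for counting, not for single-site discovery.
* Pathway curation beyond the genes named in the source screens is a
  best-effort standard-membership completion, flagged `curated`.
* Peak-level Venn counts depend on the peak dialect (summits, widths)
  produced by the upstream caller; both BED6 and narrowPeak are supported
  and the choice is explicit.
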