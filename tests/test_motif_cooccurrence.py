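import numpy as np
import pytest

from hifbind.intervals_io import TssRecord, read_fasta
from hifbind.motif_cooccurrence import (
    PWM,
    build_occurrence_matrix,
    estimate_background,
    motif_enrichment,
    promoter_windows_to_sequences,
    read_pwms,
    reverse_complement,
    scan_pwm,
    score_range,
)

BASES = "ACGT"
UNIFORM = np.full(4, 0.25)


def sharp_pwm(consensus, name="m"):
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, BASES.index(b)] = 17
    return PWM.from_counts(name, counts, pseudocount=0.5)


def naive_scan(seq, pwm, bg, frac):
    """Per-offset rescoring oracle with explicit loops."""
    lo = np.log2(pwm.matrix / bg)
    lo_min = sum(min(row) for row in lo)
    lo_max = sum(max(row) for row in lo)
    thr = lo_min + frac * (lo_max - lo_min)
    hits = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(len(seq) - pwm.length + 1):
            window = s[off: off + pwm.length]
            if "N" in window:
                continue
            score = sum(lo[i][BASES.index(b)] for i, b in enumerate(window))
            real_off = off if strand == "+" else len(seq) - pwm.length - off
            if score >= thr:
                hits.append((real_off, strand, round(score, 9)))
    return sorted(hits)


class TestPwm:
    def test_rows_sum_to_one_and_length_floor(self):
        p = sharp_pwm("ACGTA")
        assert np.allclose(p.matrix.sum(axis=1), 1.0)
        with pytest.raises(ValueError):
            PWM("bad", np.full((3, 4), 0.25), 0.5)

    def test_jaspar_round_trip_consensus(self):
        from importlib import resources

        path = resources.files("hifbind").joinpath("data/motifs/synthetic_motifs.jaspar")
        pwms = read_pwms(str(path))
        assert [p.name for p in pwms] == ["HIF", "NRF1", "SP1", "ELK1"]
        assert all(p.length == 14 for p in pwms)

    def test_reverse_complement_involution(self):
        p = sharp_pwm("ACGGTAC")
        assert np.allclose(p.reverse_complement().reverse_complement().matrix, p.matrix)


class TestScan:
    def test_consensus_scores_maximum_at_offset_zero(self):
        p = sharp_pwm("ACGTACGT")
        hits = scan_pwm(p.consensus(), p, UNIFORM, threshold_fraction=0.99)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd and fwd[0].offset == 0
        _, lo_max = score_range(p, UNIFORM)
        assert fwd[0].score == pytest.approx(lo_max)

    def test_all_n_sequence_has_no_hits(self):
        p = sharp_pwm("ACGTACGT")
        assert scan_pwm("N" * 50, p, UNIFORM) == []

    def test_motif_longer_than_sequence_is_empty(self):
        p = sharp_pwm("ACGTACGTAC")
        assert scan_pwm("ACGT", p, UNIFORM) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_rescoring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwms = [sharp_pwm("ACGTGC"), sharp_pwm("GGATCCGT"), sharp_pwm("TTACGTAA")]
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24] * 4 + [0.04]))
            for pwm in pwms:
                got = sorted(
                    (h.offset, h.strand, round(h.score, 9))
                    for h in scan_pwm(seq, pwm, UNIFORM, 0.7)
                )
                assert got == naive_scan(seq, pwm, UNIFORM, 0.7)

    def test_reverse_complement_strand_symmetry(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = sharp_pwm("ACGTGCAT")
        fwd = scan_pwm(seq, pwm, UNIFORM, 0.7)
        rev = scan_pwm(reverse_complement(seq), pwm, UNIFORM, 0.7)
        mirrored = sorted(
            (len(seq) - pwm.length - h.offset, {"+": "-", "-": "+"}[h.strand],
             round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        pwm = sharp_pwm("ACGTGCAT")
        loose = {(h.offset, h.strand) for h in scan_pwm(seq, pwm, UNIFORM, 0.6)}
        tight = {(h.offset, h.strand) for h in scan_pwm(seq, pwm, UNIFORM, 0.85)}
        assert tight <= loose


class TestPromoterExtraction:
    def test_plus_strand_window_length(self):
        genome = {"chr1": "A" * 20_000}
        recs = [TssRecord("g1", "g1", "chr1", "+", 10_000)]
        seqs = promoter_windows_to_sequences(recs, genome, 5000, 1000)
        assert len(seqs["g1"]) == 6000

    def test_minus_strand_is_reverse_complement_of_mirror(self):
        rng = np.random.default_rng(9)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        tss = 10_000
        recs = [TssRecord("g1", "g1", "chr1", "-", tss)]
        seqs = promoter_windows_to_sequences(recs, genome, 5000, 1000)
        expected = reverse_complement(genome["chr1"][tss - 1000 + 1: tss + 5000 + 1])
        assert seqs["g1"] == expected

    def test_contig_edge_truncation(self):
        genome = {"chr1": "ACGT" * 500}
        recs = [TssRecord("g1", "g1", "chr1", "+", 100)]
        seqs = promoter_windows_to_sequences(recs, genome, 5000, 1000)
        assert len(seqs["g1"]) == 1100  # upstream clipped at contig start

    def test_missing_chromosome_skipped(self):
        recs = [TssRecord("g1", "g1", "chrZ", "+", 100)]
        assert promoter_windows_to_sequences(recs, {"chr1": "ACGT" * 10}) == {}

    def test_planted_motif_recoverable_at_planted_offset(self, small_bundle):
        from hifbind.intervals_io import read_tss_table

        genome = read_fasta(small_bundle.genome)
        tss = read_tss_table(small_bundle.tss)
        pwms = read_pwms(small_bundle.motifs)
        hif = pwms[0]
        seqs = promoter_windows_to_sequences(tss, genome)
        checked = 0
        for planted in small_bundle.truth["planted_motifs"][:25]:
            seq = seqs[planted["gene"]]
            hits = scan_pwm(seq, hif, threshold_fraction=0.95,
                            sequence_name=planted["gene"])
            assert planted["promoter_offset"] in {h.offset for h in hits}
            checked += 1
        assert checked > 0


class TestEnrichment:
    def _occurrence(self, rng, n=200, rate_bound=0.8, rate_bg=0.1):
        bound = {f"b{i}" for i in range(n)}
        background = {f"u{i}" for i in range(n)}
        rows = {}
        for p in bound:
            rows[p] = [rng.random() < rate_bound]
        for p in background:
            rows[p] = [rng.random() < rate_bg]
        import pandas as pd

        from hifbind.motif_cooccurrence import OccurrenceMatrix

        table = pd.DataFrame.from_dict(rows, orient="index", columns=["m1"])
        return bound, background, OccurrenceMatrix(table, 0.8, UNIFORM)

    def test_planted_differential_rate_is_significant(self):
        rng = np.random.default_rng(11)
        bound, background, occ = self._occurrence(rng)
        results, _ = motif_enrichment(bound, background, occ)
        assert results[0].q < 0.01

    def test_absent_motif_p_is_one(self):
        rng = np.random.default_rng(12)
        bound, background, occ = self._occurrence(rng, rate_bound=0.0, rate_bg=0.0)
        results, _ = motif_enrichment(bound, background, occ)
        assert results[0].p == 1.0

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(13)
        bound, background, occ = self._occurrence(rng)
        with pytest.raises(ValueError):
            motif_enrichment(bound, bound, occ)

    def test_cooccurrence_pairs_and_jaccard(self):
        import pandas as pd

        from hifbind.motif_cooccurrence import OccurrenceMatrix

        table = pd.DataFrame(
            {"m1": [True, True, False, True], "m2": [True, False, False, True]},
            index=["b1", "b2", "b3", "b4"],
        )
        occ = OccurrenceMatrix(table, 0.8, UNIFORM)
        _, pairs = motif_enrichment({"b1", "b2", "b3", "b4"}, {"x"}, occ)
        (pair,) = pairs
        assert pair.n_both == 2 and pair.jaccard == pytest.approx(2 / 3)

    def test_background_estimate_sums_to_one(self):
        rng = np.random.default_rng(14)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=100)) for i in range(5)}
        bg = estimate_background(seqs)
        assert bg.shape == (4,) and bg.sum() == pytest.approx(1.0) and (bg > 0).all()
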