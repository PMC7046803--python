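"""PWM construction, IUPAC consensus, and log-odds scanning."""

from __future__ import annotations

import numpy as np
import pytest

from mirreg.motifs import (
    MotifHit, consensus_string, pwm_from_counts, read_counts_matrix,
    reverse_complement, scan_sequence, write_counts_matrix,
)

BASES = "ACGT"


def _random_motif(rng, length=8, name="m"):
    return pwm_from_counts(rng.integers(0, 40, size=(4, length)) + 1, name=name)


def _naive_scan(seq, motif, min_score_frac, both_strands=True):
    """Exhaustive per-window rescoring oracle, independent of the scanner."""
    lo = motif.log_odds
    L = motif.length
    threshold = min_score_frac * motif.max_score

    def score(word):
        s = 0.0
        for j, b in enumerate(word):
            s += lo[BASES.index(b), j] if b in BASES else 0.0
        return s

    hits = []
    for off in range(len(seq) - L + 1):
        w = seq[off:off + L]
        if score(w) >= threshold:
            hits.append((off, "+"))
        if both_strands and score(reverse_complement(w)) >= threshold:
            hits.append((off, "-"))
    return sorted(hits)


class TestPwm:
    def test_pure_column_scores_two_bits(self):
        m = pwm_from_counts([[10], [0], [0], [0]], pseudocount=0)
        assert m.log_odds[0, 0] == pytest.approx(2.0)  # log2(1/0.25)

    def test_uniform_column_scores_zero_for_any_pseudocount(self):
        for pc in (0.0, 0.5, 2.0):
            m = pwm_from_counts([[1], [1], [1], [1]], pseudocount=pc)
            assert np.allclose(m.log_odds, 0.0)

    def test_column_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = pwm_from_counts(rng.integers(0, 100, size=(4, 8)), pseudocount=0.5)
        assert np.allclose(m.probabilities.sum(axis=0), 1.0)

    def test_all_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="all-zero column"):
            pwm_from_counts([[0], [0], [0], [0]], pseudocount=0)

    def test_matches_biopython_pssm_scoring(self):
        """Independent cross-check of log-odds scoring against Bio.motifs."""
        from Bio import motifs as bio_motifs
        from Bio.motifs.matrix import FrequencyPositionMatrix
        from Bio.Seq import Seq
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 50, size=(4, 6)).astype(float)
        mine = pwm_from_counts(counts, pseudocount=0.5)
        bio = bio_motifs.Motif(alphabet="ACGT", counts=FrequencyPositionMatrix(
            "ACGT", {b: list(counts[i]) for i, b in enumerate(BASES)}))
        pssm = bio.counts.normalize(pseudocounts=0.5).log_odds()
        seq = "".join(rng.choice(list(BASES), 40))
        mine_scores = [
            sum(mine.log_odds[BASES.index(b), j] for j, b in enumerate(seq[o:o + 6]))
            for o in range(35)]
        bio_scores = pssm.calculate(Seq(seq))
        assert np.allclose(mine_scores, np.asarray(bio_scores)[:35], atol=1e-4)


class TestConsensus:
    @pytest.mark.parametrize("probs,expected", [
        ((0.90, 0.05, 0.03, 0.02), "A"),
        ((0.45, 0.05, 0.45, 0.05), "R"),   # A/G degenerate
        ((0.30, 0.30, 0.20, 0.20), "N"),
        ((0.05, 0.45, 0.05, 0.45), "Y"),   # C/T
    ])
    def test_per_column_rules(self, probs, expected):
        counts = np.array(probs)[:, None] * 1000
        m = pwm_from_counts(counts, pseudocount=0)
        assert consensus_string(m) == expected

    def test_multi_column(self):
        counts = np.array([[90, 45, 30], [4, 5, 30], [3, 45, 20], [3, 5, 20]])
        m = pwm_from_counts(counts, pseudocount=0)
        assert consensus_string(m) == "ARN"


class TestScan:
    def test_max_word_is_sole_hit_at_threshold_one(self):
        rng = np.random.default_rng(1)
        m = _random_motif(rng, 8)
        hits = scan_sequence(m.max_likelihood_word(), m, min_score_frac=1.0,
                             both_strands=False)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+")]
        assert hits[0].score == pytest.approx(m.max_score)

    def test_palindromic_motif_hits_in_strand_pairs(self):
        counts = np.zeros((4, 4))
        for j, b in enumerate("ACGT"):  # ACGT is its own reverse complement
            counts[BASES.index(b), j] = 20
        m = pwm_from_counts(counts)
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list(BASES), 300)) + "ACGT" + \
              "".join(rng.choice(list(BASES), 300))
        hits = scan_sequence(seq, m, min_score_frac=0.95)
        offsets = {}
        for h in hits:
            offsets.setdefault(h.offset, set()).add(h.strand)
        assert offsets and all(s == {"+", "-"} for s in offsets.values())

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        m = _random_motif(np.random.default_rng(3), 10)
        assert scan_sequence("ACGT", m) == []

    @pytest.mark.parametrize("frac", [0.0, 1.5, -1])
    def test_invalid_threshold_rejected(self, frac):
        m = _random_motif(np.random.default_rng(4), 5)
        with pytest.raises(ValueError, match="min_score_frac"):
            scan_sequence("ACGTACGTACGT", m, min_score_frac=frac)

    def test_n_bases_contribute_zero_score(self):
        m = pwm_from_counts([[10, 10], [0, 0], [0, 0], [0, 0]], pseudocount=0)
        (hit,) = scan_sequence("AN", m, min_score_frac=0.5, both_strands=False)
        assert hit.score == pytest.approx(2.0)  # A scores 2 bits, N scores 0

    def test_hit_set_equals_exhaustive_oracle_on_random_pairs(self):
        """100 random (sequence, motif) pairs vs the all-windows rescoring."""
        rng = np.random.default_rng(20)
        for _ in range(100):
            L = int(rng.integers(4, 10))
            m = _random_motif(rng, L)
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(L, 120)),
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            frac = float(rng.uniform(0.5, 1.0))
            got = sorted((h.offset, h.strand) for h in scan_sequence(seq, m, frac))
            assert got == _naive_scan(seq, m, frac)

    def test_reverse_complement_mirror_symmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            L = int(rng.integers(4, 9))
            m = _random_motif(rng, L)
            seq = "".join(rng.choice(list(BASES), size=80))
            fwd = {(h.offset, h.strand) for h in scan_sequence(seq, m, 0.7)}
            rev = {(len(seq) - L - h.offset, {"+": "-", "-": "+"}[h.strand])
                   for h in scan_sequence(reverse_complement(seq), m, 0.7)}
            assert fwd == rev

    def test_lowering_threshold_never_removes_hits(self):
        rng = np.random.default_rng(22)
        m = _random_motif(rng, 6)
        seq = "".join(rng.choice(list(BASES), size=200))
        prev: set[tuple[int, str]] = set()
        for frac in (1.0, 0.9, 0.75, 0.6, 0.4, 0.1):
            hits = {(h.offset, h.strand) for h in scan_sequence(seq, m, frac)}
            assert prev <= hits
            prev = hits

    def test_planted_occurrences_recovered_without_misses_or_spurious_hits(self, demo_bundle):
        """Peak-restricted scan at threshold 0.9 on the demo fixture finds
        exactly the embedded occurrences (motif >= 1.5 bits/column)."""
        from mirreg.motifs import scan_peaks
        assert demo_bundle.motif.information_per_column() >= 1.5
        peaks = [p for p in demo_bundle.tf_peaks
                 if p.label == demo_bundle.config.motif_tf]
        hits = scan_peaks(demo_bundle.sequences, peaks, demo_bundle.motif,
                          min_score_frac=0.9)
        assert sorted((h.seq_id, h.offset, h.strand) for h in hits) == \
            demo_bundle.truth.motif_occurrences


class TestMotifIo:
    def test_count_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        m = _random_motif(rng, 7, name="FoxA1")
        p = tmp_path / "m.pfm"
        write_counts_matrix(m, p)
        back = read_counts_matrix(p)
        assert back.name == "FoxA1"
        assert np.array_equal(back.counts, m.counts)

    def test_jaspar_style_bracket_rows_accepted(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">MA0148.1 FOXA1\nA [ 10 2 ]\nC [ 1 3 ]\nG [ 0 30 ]\nT [ 5 1 ]\n")
        m = read_counts_matrix(p)
        assert m.name == "MA0148.1" and m.length == 2
        assert m.counts[2, 1] == 30
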