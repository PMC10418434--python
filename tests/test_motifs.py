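import itertools

import numpy as np
import pytest

from deepsata.motifs import (
    BASES,
    Motif,
    MotifScanner,
    PSEUDOCOUNT,
    parse_meme,
    pvalue_table,
    rank_tfs,
    reverse_complement,
    scan_sequence,
    write_meme,
    hits_to_fimo_table,
)
from conftest import EXAMPLE_ROWS_INTERNAL, random_sequence


class TestParseMeme:
    def test_columns_reordered_to_atcg(self, meme_file):
        motifs = parse_meme(meme_file)
        assert len(motifs) == 1
        np.testing.assert_allclose(motifs[0].ppm, EXAMPLE_ROWS_INTERNAL)
        assert motifs[0].consensus == "ATCGATCGATCG"

    def test_zero_motifs(self, tmp_path):
        p = tmp_path / "empty.meme"
        p.write_text("MEME version 4\n\nALPHABET= ACGT\n")
        assert parse_meme(p) == []

    def test_uniform_motif_scores_zero_log_odds(self, tmp_path):
        p = tmp_path / "u.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF U1\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            "0.25 0.25 0.25 0.25\n0.25 0.25 0.25 0.25\n"
        )
        (m,) = parse_meme(p)
        np.testing.assert_allclose(m.log_odds(), 0.0, atol=1e-6)

    def test_bad_row_sum_rejected(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF B1\n"
            "letter-probability matrix: alength= 4 w= 1\n0.9 0.6 0.0 0.0\n"
        )
        with pytest.raises(ValueError, match="sum"):
            parse_meme(p)

    def test_missing_background_defaults_uniform(self, tmp_path):
        p = tmp_path / "nobg.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF N1\n"
            "letter-probability matrix: alength= 4 w= 1\n1.0 0.0 0.0 0.0\n"
        )
        (m,) = parse_meme(p)
        np.testing.assert_allclose(m.background, 0.25)

    def test_write_read_round_trip(self, tmp_path, example_motif):
        p = tmp_path / "rt.meme"
        write_meme([example_motif], p)
        (back,) = parse_meme(p)
        np.testing.assert_allclose(back.ppm, example_motif.ppm, atol=1e-6)
        assert back.id == example_motif.id


class TestPvalueTable:
    def test_length_one_motif_max_score_pvalue(self):
        m = Motif("A1", "A1", np.array([[0.97, 0.01, 0.01, 0.01]]))
        t = pvalue_table(m)
        # only A attains the maximal score under a uniform background
        assert t.pvalue_of_int(t.max_int_score) == pytest.approx(0.25)

    def test_tail_non_increasing(self, example_motif):
        t = pvalue_table(example_motif)
        assert (np.diff(t.tail) <= 1e-12).all()

    def test_matches_exhaustive_trinucleotide_enumeration(self):
        """DP tail equals direct enumeration over all 64 trinucleotides."""
        rng = np.random.default_rng(5)
        ppm = rng.dirichlet(np.ones(4), size=3)
        bg = np.array([0.3, 0.3, 0.2, 0.2])
        m = Motif("T1", "T1", ppm, bg)
        t = pvalue_table(m, n_bins=2000)
        lo = np.log2((ppm + PSEUDOCOUNT) / (ppm + PSEUDOCOUNT).sum(1, keepdims=True) / bg)
        words = list(itertools.product(range(4), repeat=3))
        scores = np.array([lo[0, w[0]] + lo[1, w[1]] + lo[2, w[2]] for w in words])
        probs = np.array([bg[w[0]] * bg[w[1]] * bg[w[2]] for w in words])
        for w, s in zip(words, scores):
            exact = probs[scores >= s - 1e-9].sum()
            # compare at the integer score of this exact word
            int_s = int(t.int_matrix[np.arange(3), list(w)].sum())
            assert t.pvalue_of_int(int_s) == pytest.approx(exact, abs=2e-2)

    def test_n_bins_precondition(self, example_motif):
        with pytest.raises(ValueError):
            pvalue_table(example_motif, n_bins=10)


def naive_scan(seq, motif, p_threshold=1e-4, n_bins=1000):
    """All-windows oracle: python loops, independent of the vectorized path."""
    hits = []
    L = len(motif)
    for strand in "+-":
        mo = motif if strand == "+" else motif.reverse_complement()
        table = pvalue_table(mo, background=motif.background, n_bins=n_bins)
        for s in range(len(seq) - L + 1):
            word = seq[s : s + L]
            int_score = sum(
                table.int_matrix[i, "ATCGN".index(b)] for i, b in enumerate(word)
            )
            p = float(table.pvalue_of_int(int_score))
            if p <= p_threshold:
                hits.append((s, strand, p))
    return sorted(hits)


class TestScanSequence:
    def test_planted_consensus_found_at_offset(self, example_motif, rng):
        bg = random_sequence(rng, 200)
        seq = bg[:37] + example_motif.consensus + bg[49:200]
        hits = [h for h in scan_sequence(seq, example_motif, p_threshold=1e-6)
                if h.strand == "+"]
        assert [h.start for h in hits] == [37]
        assert hits[0].matched_seq == example_motif.consensus

    def test_all_n_sequence_has_no_hits(self, example_motif):
        assert scan_sequence("N" * 100, example_motif) == []

    def test_short_sequence_returns_empty(self, example_motif):
        assert scan_sequence("ACGT", example_motif) == []

    def test_palindromic_motif_pairs_strands(self):
        ppm = np.zeros((4, 4))
        # consensus ATAT whose reverse complement is ATAT
        for i, b in enumerate("ATAT"):
            ppm[i, BASES.index(b)] = 0.97
            ppm[i, [j for j in range(4) if j != BASES.index(b)]] = 0.01
        m = Motif("P1", "P1", ppm)
        seq = "GGGGG" + "ATAT" + "GGGGG"
        hits = scan_sequence(seq, m, p_threshold=1e-2)
        by_start = {}
        for h in hits:
            by_start.setdefault(h.start, set()).add(h.strand)
        assert all(strands == {"+", "-"} for strands in by_start.values())

    def test_agrees_with_all_windows_oracle(self, rng):
        """Vectorized scanning equals the naive per-window oracle (<=500 bp)."""
        ppm = rng.dirichlet(np.ones(4) * 0.3, size=8)
        m = Motif("R1", "R1", ppm)
        for trial in range(3):
            seq = random_sequence(rng, 500)
            # plant one consensus to guarantee some hits
            seq = seq[:100] + m.consensus + seq[100 + len(m):]
            got = sorted((h.start, h.strand, h.pvalue) for h in scan_sequence(seq, m, p_threshold=1e-3))
            expected = naive_scan(seq, m, p_threshold=1e-3)
            assert [(s, st) for s, st, _ in got] == [(s, st) for s, st, _ in expected]
            np.testing.assert_allclose(
                [p for *_, p in got], [p for *_, p in expected], rtol=1e-9
            )

    def test_fimo_export_is_one_based_inclusive(self, example_motif, rng):
        seq = "A" * 20 + example_motif.consensus + "A" * 20
        hits = scan_sequence(seq, example_motif, p_threshold=1e-6, chrom="w1")
        table = hits_to_fimo_table(hits)
        row = table.iloc[0]
        assert row["start"] == 21 and row["stop"] == 32


class TestRankTfs:
    def _hits(self, motif_id, n):
        from deepsata.motifs import MotifHit
        return [MotifHit(motif_id, "b", i, "+", 1.0, 1e-5, "A") for i in range(n)]

    def test_higher_count_ranks_first(self):
        motifs = [Motif(i, i, np.full((2, 4), 0.25)) for i in ("X", "Y")]
        bins = [{"X": self._hits("X", 10), "Y": self._hits("Y", 2)}]
        r = rank_tfs(bins, motifs, n=2)
        assert r.ranking[0] == ("X", 10)

    def test_ties_broken_lexicographically(self):
        motifs = [Motif(i, i, np.full((2, 4), 0.25)) for i in ("Y", "X")]
        bins = [{"X": self._hits("X", 5), "Y": self._hits("Y", 5)}]
        r = rank_tfs(bins, motifs, n=2)
        assert [mid for mid, _ in r.ranking] == ["X", "Y"]

    def test_top_k_matches_brute_force(self, rng):
        motifs = [Motif(f"M{i}", f"M{i}", np.full((2, 4), 0.25)) for i in range(5)]
        bins = []
        for _ in range(20):
            bins.append(
                {m.id: self._hits(m.id, int(rng.integers(0, 4))) for m in motifs}
            )
        r = rank_tfs(bins, motifs, n=3)
        brute = sorted(
            ((sum(len(b[m.id]) for b in bins), m.id) for m in motifs),
            key=lambda t: (-t[0], t[1]),
        )
        assert [mid for mid, _ in r.ranking[:3]] == [mid for _, mid in brute[:3]]

    def test_bins_mode_counts_bins_not_hits(self):
        motifs = [Motif(i, i, np.full((2, 4), 0.25)) for i in ("X", "Y")]
        bins = [
            {"X": self._hits("X", 10), "Y": self._hits("Y", 1)},
            {"X": [], "Y": self._hits("Y", 1)},
        ]
        r = rank_tfs(bins, motifs, n=2, mode="bins")
        assert r.ranking[0] == ("Y", 2)

    def test_selected_n_capped_by_presence(self):
        motifs = [Motif(i, i, np.full((2, 4), 0.25)) for i in ("X", "Y")]
        bins = [{"X": self._hits("X", 3), "Y": []}]
        r = rank_tfs(bins, motifs, n=5)
        assert r.selected_n == 1

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            rank_tfs([], [], n=3)


def test_scanner_doubling_nbins_keeps_decisions(example_motif, rng):
    """Hit/no-hit decisions are stable when the score discretization is refined."""
    seq = random_sequence(rng, 400)
    seq = seq[:50] + example_motif.consensus + seq[62:]
    h1 = {(h.start, h.strand) for h in scan_sequence(seq, example_motif, n_bins=1000)}
    h2 = {(h.start, h.strand) for h in scan_sequence(seq, example_motif, n_bins=2000)}
    assert h1 == h2


def test_reverse_complement_involution(example_motif):
    rc2 = example_motif.reverse_complement().reverse_complement()
    np.testing.assert_allclose(rc2.ppm, example_motif.ppm)
    assert reverse_complement(reverse_complement("ACGTN")) == "ACGTN"
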