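"""PFM I/O, similarity/clustering, UTR scanning, seed matching, enrichment."""

import numpy as np
import pytest
from scipy import stats

from introdelta import (
    PFM,
    MotifScanner,
    UTRSet,
    cluster_pfms,
    enrichment_test,
    kmer_sites,
    load_utrs,
    mirna_seed_pattern,
    pfm_similarity,
    read_pfms,
    scan_affinity,
    write_pfms,
)
from introdelta.motifs import _random_panel, _panel_scores

from conftest import random_pfm


MEME_UNIFORM = """MEME version 4

ALPHABET= ACGT

MOTIF UNI uniform
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
"""


class TestPFMIO:
    def test_meme_readback(self):
        pfms = read_pfms(MEME_UNIFORM, "meme")
        assert len(pfms) == 1
        assert pfms[0].length == 4
        assert np.allclose(pfms[0].matrix, 0.25)

    def test_counts_normalized(self):
        table = ">M1 X\n2 0 0 2\n2 0 0 2\n2 0 0 2\n"
        p = read_pfms(table, "table")[0]
        assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)
        # zero cells floored by the pseudocount, then renormalized
        assert (p.matrix > 0).all()
        assert p.matrix[0, 0] == pytest.approx(p.matrix[0, 3])
        assert p.matrix[0, 0] > 0.49

    @pytest.mark.parametrize("fmt", ["meme", "table"])
    def test_round_trip(self, fmt, rng):
        pfms = [random_pfm(f"M{i}", rng) for i in range(4)]
        back = read_pfms(write_pfms(pfms, fmt), fmt)
        for a, b in zip(pfms, back):
            assert a.motif_id == b.motif_id
            assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_zero_row_is_error(self):
        with pytest.raises(ValueError, match="position 2"):
            PFM("B", "B", np.array([[1, 0, 0, 0], [0, 0, 0, 0],
                                    [1, 0, 0, 0]], dtype=float))

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="length"):
            PFM("S", "S", np.full((2, 4), 0.25))


class TestSimilarityClustering:
    def test_self_similarity(self, simple_pfm):
        assert pfm_similarity(simple_pfm, simple_pfm) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = random_pfm("A", rng), random_pfm("B", rng)
        assert pfm_similarity(a, b) == pytest.approx(pfm_similarity(b, a),
                                                     abs=1e-12)

    def test_uniform_is_degenerate(self, simple_pfm):
        uni = read_pfms(MEME_UNIFORM, "meme")[0]
        assert pfm_similarity(uni, simple_pfm) == 0.0

    def test_matches_recomputed_correlation(self, rng):
        a, b = random_pfm("A", rng), random_pfm("B", rng)
        panel = _random_panel(500, 100, 0)
        sa = np.array([scan_affinity(a, s).affinity for s in panel])
        sb = np.array([scan_affinity(b, s).affinity for s in panel])
        expected = stats.pearsonr(sa, sb).statistic
        assert pfm_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_threshold_above_one_isolates(self, rng):
        pfms = [random_pfm(f"M{i}", rng) for i in range(4)]
        reps, cmap = cluster_pfms(pfms, threshold=1.1)
        assert len(reps) == 4
        assert all(cmap[p.motif_id] == p.motif_id for p in pfms)

    def test_duplicates_merge(self, rng):
        p = random_pfm("A", rng)
        dup = PFM("A2", "A2", p.matrix.copy())
        reps, cmap = cluster_pfms([p, dup])
        assert len(reps) == 1
        assert cmap["A2"] == "A"

    def test_matches_greedy_oracle(self, rng):
        """Planted near-identical pairs co-cluster; assignment equals a
        hand-run greedy trace over the same similarity matrix."""
        base = [random_pfm(f"M{i}", rng) for i in range(6)]
        noisy = []
        for i in (0, 2):
            m = base[i].matrix + rng.normal(0, 0.01, base[i].matrix.shape)
            noisy.append(PFM(f"M{i}x", f"M{i}x", np.abs(m)))
        pfms = base + noisy
        reps, cmap = cluster_pfms(pfms, threshold=0.75)
        assert cmap["M0x"] == "M0" and cmap["M2x"] == "M2"
        # greedy trace oracle
        panel = _random_panel(500, 100, 0)
        scores = {p.motif_id: _panel_scores(p, panel) for p in pfms}
        oracle_reps, oracle_map = [], {}
        for p in pfms:
            for r in oracle_reps:
                if np.corrcoef(scores[p.motif_id], scores[r])[0, 1] >= 0.75:
                    oracle_map[p.motif_id] = r
                    break
            else:
                oracle_reps.append(p.motif_id)
                oracle_map[p.motif_id] = p.motif_id
        assert cmap == oracle_map


class TestScanAffinity:
    def test_consensus_certainty_motif(self):
        # near-certainty PFM: max window score ~1 at the consensus
        m = np.full((4, 4), 1e-9)
        m[:, 0] = 1.0  # AAAA
        p = PFM("AA", "AA", m)
        res = scan_affinity(p, "GGGAAAAGGG")
        assert res.presence
        assert res.best_window == 3

    def test_short_sequence(self, simple_pfm):
        res = scan_affinity(simple_pfm, "AT")
        assert res == (0.0, False, None)

    def test_window_enumeration_oracle(self, rng):
        p = random_pfm("R", rng)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        res = scan_affinity(p, seq)
        scores = []
        for i in range(len(seq) - p.length + 1):
            w = seq[i:i + p.length]
            scores.append(np.prod([p.matrix[j, "ACGT".index(ch)]
                                   for j, ch in enumerate(w)]))
        assert res.affinity == pytest.approx(np.log2(np.sum(scores)),
                                             abs=1e-9)
        assert res.best_window == int(np.argmax(scores))

    def test_u_and_t_equivalent(self, simple_pfm):
        seq_t = "GGATTTAGGATTTAGG"
        seq_u = seq_t.replace("T", "U")
        assert scan_affinity(simple_pfm, seq_t) == \
            scan_affinity(simple_pfm, seq_u)

    def test_position_covariance(self, simple_pfm, rng):
        """Prepending low-scoring bases changes affinity only by the added
        windows' near-zero scores."""
        seq = "GG" + simple_pfm.consensus + "GG"
        res1 = scan_affinity(simple_pfm, seq)
        res2 = scan_affinity(simple_pfm, "GCGC" + seq)
        assert res2.affinity == pytest.approx(res1.affinity, abs=0.1)
        assert res2.best_window == res1.best_window + 4

    def test_planted_ranks_above_random(self, rng):
        """UTRs with a planted consensus outscore length-matched random UTRs."""
        m = np.full((7, 4), 0.02)
        m[np.arange(7), [0, 2, 1, 3, 0, 2, 1]] = 0.94  # sharp AGCTAGC motif
        pfm = PFM("SHARP", "SHARP", m)
        wins = 0
        for _ in range(100):
            bg = "".join("ACGT"[b] for b in rng.integers(0, 4, 80))
            pos = rng.integers(0, 80 - pfm.length)
            planted = bg[:pos] + pfm.consensus + bg[pos + pfm.length:]
            other = "".join("ACGT"[b] for b in rng.integers(0, 4, 80))
            if scan_affinity(pfm, planted).affinity > \
                    scan_affinity(pfm, other).affinity:
                wins += 1
        assert wins >= 95


class TestKmerSites:
    def test_single_occurrence(self):
        count, pos = kmer_sites("ATTTA", "GGGATTTAGGG")
        assert (count, pos) == (1, [3])

    def test_absent(self):
        assert kmer_sites("ATTTA", "GGGGGG")[0] == 0

    def test_overlapping_matches_sliding_oracle(self):
        count, pos = kmer_sites("AAA", "AAAAA")
        assert (count, pos) == (3, [0, 1, 2])
        seq = "AAATAAAA"
        expected = [i for i in range(len(seq) - 2) if seq[i:i + 3] == "AAA"]
        assert kmer_sites("AAA", seq)[1] == expected

    def test_iupac_degenerate(self):
        count, pos = kmer_sites("WTTTA", "GATTTAGTTTTAG")
        assert count == 2  # ATTTA and TTTTA

    def test_invalid_letter(self):
        with pytest.raises(ValueError, match="IUPAC"):
            kmer_sites("AXA", "AAA")

    def test_empty_pattern(self):
        with pytest.raises(ValueError, match="empty"):
            kmer_sites("", "AAA")


class TestSeedPattern:
    def test_7mer_m8_is_revcomp_of_2_8(self):
        # miR-9-5p: UCUUUGGUUAUCUAGCUGUAUGA; seed 2-8 = CUUUGGU
        assert mirna_seed_pattern("UCUUUGGUUAUCUAGCUGUAUGA") == "ACCAAAG"

    def test_8mer_and_7mer_a1(self):
        mir = "UCUUUGGUU"
        assert mirna_seed_pattern(mir, "8mer") == "ACCAAAGA"
        assert mirna_seed_pattern(mir, "7mer-A1") == "CCAAAGA"

    def test_too_short(self):
        with pytest.raises(ValueError, match="8 nt"):
            mirna_seed_pattern("ACGUACG")


class TestEnrichment:
    def test_no_association(self):
        res = enrichment_test(10, 20, 20, 40)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(stats.hypergeom.sf(9, 40, 20, 20))

    def test_matches_hypergeometric_tail(self):
        """All hits inside the set: p equals the direct hypergeometric sum."""
        res = enrichment_test(5, 10, 5, 100)
        N, K, n = 100, 5, 10  # universe, hits total, set size
        tail = sum(stats.hypergeom.pmf(k, N, K, n) for k in range(5, 6))
        assert res.p == pytest.approx(tail, rel=1e-9)
        assert res.haldane  # zero cell -> corrected OR, flagged

    def test_empty_set_error(self):
        with pytest.raises(ValueError, match="empty"):
            enrichment_test(0, 0, 5, 100)

    def test_universe_zero_error(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_test(0, 0, 0, 0)

    def test_sample_odds_ratio(self):
        res = enrichment_test(8, 10, 10, 110)
        # table [[8,2],[2,98]]
        assert res.odds_ratio == pytest.approx(8 * 98 / (2 * 2))
        assert not res.haldane


class TestUTRSetAndScanner:
    def test_load_fasta(self):
        utrs = load_utrs(">G1\nACGUACGU\n>G2\nTTTT\n")
        assert utrs.sequences["G1"] == "ACGTACGT"  # U normalized to T

    def test_eligible_empty_sequence_error(self):
        with pytest.raises(ValueError, match="empty"):
            UTRSet(sequences={"G1": ""}, eligible={"G1": True})

    def test_scanner_matrix_matches_scan_affinity(self, rng, simple_pfm):
        seqs = {f"G{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 50))
                for i in range(5)}
        utrs = UTRSet(sequences=seqs)
        scanner = MotifScanner(pfms=[simple_pfm]).fit()
        aff, pres, sites = scanner.scan(utrs)
        for g, s in seqs.items():
            res = scan_affinity(simple_pfm, s)
            assert aff.loc[g, "M001"] == pytest.approx(res.affinity)
            assert pres.loc[g, "M001"] == res.presence

    def test_ineligible_genes_excluded(self, simple_pfm):
        utrs = UTRSet(sequences={"A": "ACGTACGTACGT", "B": "ACGTACGTACGT"},
                      eligible={"A": True, "B": False})
        aff = MotifScanner(pfms=[simple_pfm]).fit().transform(utrs)
        assert list(aff.index) == ["A"]
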