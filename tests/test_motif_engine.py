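import itertools

import numpy as np
import pytest
from scipy import stats

from trninfer import motif_engine as me
from trninfer.genome_io import IntergenicRegion


def _igr(seq, gene="g0", genome="t"):
    return IntergenicRegion(gene_id=gene, genome_id=genome, replicon_id="r", sequence=seq, upstream_of_strand="+")


class TestBackground:
    def test_all_a_order0(self):
        bg = me.train_background(["A" * 100], order=0)
        # 100 A's + 1 pseudocount per base
        assert bg.stationary[0] == pytest.approx(101 / 104)

    def test_order0_hand_count_on_12mer(self):
        bg = me.train_background(["AAAACCCGGTTA"], order=0)
        np.testing.assert_allclose(bg.stationary, [6 / 16, 4 / 16, 3 / 16, 3 / 16])

    def test_uniform_iid_order3_transitions(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40000)) for _ in range(4)]
        bg = me.train_background(seqs, order=3)
        assert np.abs(bg.cond[3] - 0.25).max() < 0.05

    def test_transition_rows_sum_to_one(self, trained_bg):
        for k in range(trained_bg.order + 1):
            np.testing.assert_allclose(trained_bg.cond[k].sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            me.train_background([], order=2)

    def test_window_logprobs_match_direct_product(self, trained_bg):
        seq = "ACGTACGGTTACATGCAT"
        enc = me.encode(seq)
        lp = trained_bg.window_logprobs(enc, 5)
        # direct computation for the window starting at position 6
        i0 = 6
        expect = 0.0
        for i in range(i0, i0 + 5):
            k = min(3, i)
            ctx = 0
            for j in range(i - k, i):
                ctx = ctx * 4 + enc[j]
            expect += np.log(trained_bg.cond[k][ctx, enc[i]])
        assert lp[i0] == pytest.approx(expect)


class TestBuildPssm:
    def test_single_site_one_hot(self):
        p = me.build_pssm(["ACGT"], pseudocount=0)
        np.testing.assert_allclose(p.freqs, np.eye(4)[:, [0, 1, 2, 3]])

    def test_two_sites_half_half(self):
        p = me.build_pssm(["AA", "AC"], pseudocount=0)
        assert p.freqs[0, 0] == 1.0
        assert p.freqs[0, 1] == 0.5 and p.freqs[1, 1] == 0.5

    def test_matches_independent_tally(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 7)) for _ in range(10)]
        p = me.build_pssm(sites, pseudocount=0.25)
        for j in range(7):
            for b, base in enumerate("ACGT"):
                count = sum(1 for s in sites if s[j] == base)
                assert p.freqs[b, j] == pytest.approx((count + 0.25) / (10 + 1.0))

    def test_unequal_widths_rejected(self):
        with pytest.raises(ValueError, match="equal widths"):
            me.build_pssm(["ACGT", "ACG"])

    def test_columns_sum_to_one(self, rng):
        p = me.build_pssm(["".join(rng.choice(list("ACGT"), 9)) for _ in range(5)])
        np.testing.assert_allclose(p.freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_revcomp_involution(self, rng):
        p = me.build_pssm(["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)])
        np.testing.assert_allclose(p.revcomp().revcomp().freqs, p.freqs)


class TestScoreDistribution:
    def test_one_hot_max_score_pvalue_by_enumeration(self, uniform_bg):
        pssm = me.build_pssm(["ACGT"], pseudocount=0, motif_id="oh")
        dist = me._ScoreDistribution(pssm, uniform_bg.stationary)
        max_score = dist.s_int.max(axis=0).sum()
        assert dist.pvalue(np.array([max_score]))[0] == pytest.approx(0.25**4)

    def test_full_distribution_matches_word_enumeration(self, rng, uniform_bg):
        """Exact DP survival equals brute-force enumeration of all 256 words."""
        sites = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(6)]
        pssm = me.build_pssm(sites, pseudocount=0.25, motif_id="w4")
        dist = me._ScoreDistribution(pssm, uniform_bg.stationary)
        word_scores = []
        for word in itertools.product(range(4), repeat=4):
            word_scores.append(dist.s_int[list(word), np.arange(4)].sum())
        word_scores = np.array(word_scores)
        for s in np.unique(word_scores):
            brute = (word_scores >= s).sum() / 256
            assert dist.pvalue(np.array([s]))[0] == pytest.approx(brute, abs=1e-12)

    def test_pvalue_monotone_in_score(self, rng, uniform_bg):
        pssm = me.build_pssm(["".join(rng.choice(list("ACGT"), 6)) for _ in range(5)])
        dist = me._ScoreDistribution(pssm, uniform_bg.stationary)
        grid = np.arange(dist.base, dist.base + dist.sf.size, 50)
        ps = dist.pvalue(grid)
        assert (np.diff(ps) <= 1e-15).all()


class TestScanForHits:
    def test_consensus_word_is_top_hit(self, rng, uniform_bg):
        sites = ["TGACGTCA"] * 5
        pssm = me.build_pssm(sites, motif_id="m")
        flank = "".join(rng.choice(list("ACGT"), 40))
        seq = flank + "TGACGTCA" + flank
        hits = me.scan_for_hits(pssm, [_igr(seq)], uniform_bg, p_max=1e-3)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].offset == 40

    def test_minus_strand_mirrors_plus_on_revcomp(self, rng, uniform_bg):
        from trninfer.genome_io import revcomp

        sites = ["TGACGTAG"] * 4
        pssm = me.build_pssm(sites, motif_id="m")
        seq = "".join(rng.choice(list("ACGT"), 30)) + "TGACGTAG" + "".join(rng.choice(list("ACGT"), 30))
        fwd = me.scan_for_hits(pssm, [_igr(seq)], uniform_bg, p_max=1.0)
        rev = me.scan_for_hits(pssm, [_igr(revcomp(seq))], uniform_bg, p_max=1.0)
        best_fwd = max(fwd, key=lambda h: h.score)
        best_rev = max(rev, key=lambda h: h.score)
        assert best_fwd.score == pytest.approx(best_rev.score)
        assert {best_fwd.strand, best_rev.strand} == {"+", "-"}
        # same site in replicon coordinates
        assert best_rev.offset == len(seq) - 8 - best_fwd.offset

    def test_windows_with_n_skipped(self, uniform_bg):
        pssm = me.build_pssm(["ACGTAC"] * 3, motif_id="m")
        hits = me.scan_for_hits(pssm, [_igr("NNNNNNNNNN")], uniform_bg, p_max=1.0)
        assert hits == []

    def test_best_hit_pvalues_uniform_under_null(self, uniform_bg):
        """Best-hit word p-values transformed by the analytic best-of-L map
        1-(1-p)^L are uniform on background sequences (KS at alpha=0.01)."""
        r = np.random.default_rng(11)
        sites = ["".join(r.choice(list("ACGT"), 12)) for _ in range(20)]
        pssm = me.build_pssm(sites, motif_id="x")
        igrs = [_igr("".join(r.choice(list("ACGT"), 150)), gene=f"g{i}") for i in range(300)]
        hits = me.scan_for_hits(pssm, igrs, uniform_bg, p_max=1.0)
        L = 150 - 12 + 1
        ps = np.array([h.p_value for h in hits])
        corrected = 1 - (1 - ps) ** L
        assert stats.kstest(corrected, "uniform").pvalue > 0.01


class TestDiscovery:
    def test_planted_8mer_consensus_recovered(self, trained_bg):
        r = np.random.default_rng(3)
        planted = "TGACGTCA"
        seqs = []
        for i in range(8):
            s = trained_bg.sample(60, r)
            if i < 6:
                off = int(r.integers(0, 52))
                s = s[:off] + planted + s[off + 8 :]
            seqs.append(s)
        found = me.discover_motifs_zoops(seqs, trained_bg, widths=(8,), seed=1, n_null=8)
        assert found and found[0].pssm.consensus == planted

    def test_two_planted_motifs_both_recovered(self, trained_bg):
        r = np.random.default_rng(4)
        m1, m2 = "TGACGTCA", "CCCTATAGGG"
        seqs = []
        for i in range(8):
            s = trained_bg.sample(90, r)
            o1 = int(r.integers(0, 30))
            o2 = int(r.integers(50, 80))
            s = s[:o1] + m1 + s[o1 + 8 :]
            s = s[:o2] + m2 + s[o2 + 10 :]
            seqs.append(s)
        found = me.discover_motifs_zoops(seqs, trained_bg, nmotifs=3, widths=(8, 10), seed=2, n_null=8)
        consensi = [f.pssm.consensus for f in found]
        assert any(m1 in c or c in m1 for c in consensi)
        assert any(m2 in c or c in m2 for c in consensi)

    def test_pure_background_mostly_empty(self, trained_bg):
        """On background-only groups the discovery false-positive rate at
        E-value 0.01 stays at or below 5% (100 seeded replicates)."""
        r = np.random.default_rng(5)
        n_found = 0
        for rep in range(100):
            seqs = [trained_bg.sample(60, r) for _ in range(6)]
            found = me.discover_motifs_zoops(seqs, trained_bg, widths=(8,), seed=100 + rep, n_null=6)
            n_found += bool(found)
        assert n_found <= 5

    def test_round_trip_rebuilt_pssm_close_to_planted(self, trained_bg):
        """PSSM rebuilt from discovered sites has per-column total-variation
        distance < 0.1 from the planted PSSM over the aligned overlap."""
        r = np.random.default_rng(6)
        planted_sites = ["TGACGTCA"] * 20
        planted = me.build_pssm(planted_sites, pseudocount=0.25, motif_id="planted")
        seqs = []
        for i in range(10):
            s = trained_bg.sample(70, r)
            off = int(r.integers(0, 62))
            seqs.append(s[:off] + "TGACGTCA" + s[off + 8 :])
        found = me.discover_motifs_zoops(seqs, trained_bg, widths=(8,), seed=3, n_null=8)
        assert found
        rebuilt = found[0].pssm
        cmp = me.compare_pssms(planted, rebuilt, n_shuffle=200, seed=0)
        # align columns using the best offset/orientation
        b = rebuilt if cmp.orientation == "forward" else rebuilt.revcomp()
        for i in range(planted.width):
            j = i - cmp.offset
            if 0 <= j < b.width:
                tv = 0.5 * np.abs(planted.freqs[:, i] - b.freqs[:, j]).sum()
                assert tv < 0.1


class TestComparePssms:
    def test_self_comparison(self, rng):
        a = me.build_pssm(["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)], motif_id="a")
        res = me.compare_pssms(a, a, n_shuffle=500, seed=0)
        assert res.offset == 0 and res.orientation == "forward"
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_revcomp_detected(self, rng):
        a = me.build_pssm(["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)], motif_id="a")
        res = me.compare_pssms(a, a.revcomp(), n_shuffle=500, seed=0)
        assert res.orientation == "reverse"
        assert res.statistic == pytest.approx(1.0)

    def test_one_hot_vs_uniform_not_significant(self):
        onehot = me.build_pssm(["ACGTACGT"] * 10, pseudocount=0, motif_id="oh")
        uniform = me.PSSM(motif_id="u", counts=np.full((4, 8), 5.0), n_sites=20)
        res = me.compare_pssms(onehot, uniform, n_shuffle=500, seed=1)
        assert res.p_value > 0.2

    def test_statistic_invariant_under_joint_revcomp(self, rng):
        a = me.build_pssm(["".join(rng.choice(list("ACGT"), 9)) for _ in range(4)], motif_id="a")
        b = me.build_pssm(["".join(rng.choice(list("ACGT"), 7)) for _ in range(4)], motif_id="b")
        res = me.compare_pssms(a, b, n_shuffle=100, seed=0)
        res_rc = me.compare_pssms(a.revcomp(), b.revcomp(), n_shuffle=100, seed=0)
        assert res.statistic == pytest.approx(res_rc.statistic, abs=1e-9)


class TestQvalues:
    def test_all_zero(self):
        np.testing.assert_allclose(me.qvalues([0.0, 0.0, 0.0]), 0.0)

    def test_hand_bh(self):
        np.testing.assert_allclose(me.qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        q = me.qvalues(p)
        assert (q >= p - 1e-12).all()

    def test_monotone_in_p_rank(self, rng):
        p = np.sort(rng.random(30))
        q = me.qvalues(p)
        assert (np.diff(q) >= -1e-12).all()


class TestClusterMotifs:
    def _pssm(self, mid, rng):
        return me.build_pssm(["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)], motif_id=mid)

    def test_identical_hit_sets_merge(self, rng):
        a, b = self._pssm("a", rng), self._pssm("b", rng)
        hits = {"a": {("g1", 0), ("g2", 3)}, "b": {("g1", 0), ("g2", 3)}}
        q = {frozenset(("a", "b")): 0.001}
        clusters = me.cluster_motifs([a, b], hits, q)
        assert len(clusters) == 1 and clusters[0].members == ["a", "b"]

    def test_low_overlap_stays_separate(self, rng):
        a, b = self._pssm("a", rng), self._pssm("b", rng)
        hits = {"a": {("g1", 0), ("g2", 3), ("g3", 1), ("g4", 9), ("g5", 2)}, "b": {("g1", 0), ("g6", 5), ("g7", 1), ("g8", 4), ("g9", 7)}}
        q = {frozenset(("a", "b")): 0.001}
        clusters = me.cluster_motifs([a, b], hits, q, min_overlap=0.33)
        assert len(clusters) == 2

    def test_single_motif_singleton(self, rng):
        a = self._pssm("a", rng)
        clusters = me.cluster_motifs([a], {"a": {("g1", 0)}}, {})
        assert len(clusters) == 1 and clusters[0].members == ["a"]

    def test_high_overlap_but_poor_q_stays_separate(self, rng):
        a, b = self._pssm("a", rng), self._pssm("b", rng)
        hits = {"a": {("g1", 0)}, "b": {("g1", 0)}}
        q = {frozenset(("a", "b")): 0.5}
        assert len(me.cluster_motifs([a, b], hits, q)) == 2

    def test_invariant_to_input_order(self, rng):
        motifs = [self._pssm(m, rng) for m in "abc"]
        hits = {"a": {("g1", 0)}, "b": {("g1", 0)}, "c": {("g9", 2)}}
        q = {frozenset(("a", "b")): 0.001, frozenset(("a", "c")): 0.9, frozenset(("b", "c")): 0.9}
        c1 = me.cluster_motifs(motifs, hits, q)
        c2 = me.cluster_motifs(motifs[::-1], hits, q)
        assert [c.members for c in c1] == [c.members for c in c2]
        assert len(c1) <= len(motifs)

    def test_overlap_coefficient_uses_smaller_set(self):
        a = {("g1", 0), ("g2", 0), ("g3", 0)}
        b = {("g1", 0), ("g4", 0), ("g5", 0), ("g6", 0), ("g7", 0), ("g8", 0)}
        assert me.overlap_coefficient(a, b) == pytest.approx(1 / 3)

    def test_overlap_tolerates_adjacent_bins(self):
        a = {("g1", 4)}
        b = {("g1", 5)}
        assert me.overlap_coefficient(a, b) == 1.0


def test_meme_minimal_round_trip(tmp_path, rng):
    pssms = [
        me.build_pssm(["".join(rng.choice(list("ACGT"), 8)) for _ in range(6)], motif_id=f"m{k}")
        for k in range(3)
    ]
    path = tmp_path / "motifs.meme"
    me.write_meme_minimal(pssms, path)
    back = me.read_meme_minimal(path)
    assert [p.motif_id for p in back] == [p.motif_id for p in pssms]
    for orig, new in zip(pssms, back):
        np.testing.assert_allclose(new.freqs, orig.freqs, atol=0.05)
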