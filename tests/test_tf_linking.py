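import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trninfer import motif_engine as me
from trninfer.expression import Bicluster
from trninfer.genome_io import OrthologGroup
from trninfer.tf_linking import (
    PermutationNull,
    ReferenceMotifLibrary,
    TFClusterScore,
    TFRecord,
    build_nulls,
    corr_mean,
    dbd_score,
    library_qvalues,
    motif_occurrence_vectors,
    permutation_pvalue,
    phylo_corr,
    prox_min,
    r_score,
    rank_tfs_for_cluster,
)

from conftest import make_genes


def _bicluster(genes, conds):
    return Bicluster(cluster_id="C0", genes=set(genes), conditions=set(conds), mean_abs_pairwise_corr=0.9)


class TestCorrMean:
    def test_identical_profiles(self):
        m = pd.DataFrame([[1.0, 2, 3, 4]] * 3, index=["tf", "a", "b"], columns=list("wxyz"))
        tf = TFRecord(tf_id="tf")
        assert corr_mean(tf, _bicluster(["a", "b"], "wxyz"), m) == pytest.approx(1.0)

    def test_exact_negation_gives_one(self):
        m = pd.DataFrame([[1.0, 2, 3, 4], [-1, -2, -3, -4]], index=["tf", "a"], columns=list("wxyz"))
        assert corr_mean(TFRecord(tf_id="tf"), _bicluster(["a"], "wxyz"), m) == pytest.approx(1.0)

    def test_hand_pearson_two_genes(self):
        m = pd.DataFrame(
            [[1.0, 2, 3, 5], [2, 1, 4, 3], [0, 1, 1, 3]],
            index=["tf", "a", "b"],
            columns=list("wxyz"),
        )
        ra = abs(np.corrcoef([1, 2, 3, 5], [2, 1, 4, 3])[0, 1])
        rb = abs(np.corrcoef([1, 2, 3, 5], [0, 1, 1, 3])[0, 1])
        got = corr_mean(TFRecord(tf_id="tf"), _bicluster(["a", "b"], "wxyz"), m)
        assert got == pytest.approx((ra + rb) / 2)

    def test_tf_not_on_array_undefined(self):
        m = pd.DataFrame([[1.0, 2, 3, 4]], index=["a"], columns=list("wxyz"))
        assert corr_mean(TFRecord(tf_id="tf"), _bicluster(["a"], "wxyz"), m) is None

    def test_tf_excluded_from_own_cluster(self):
        m = pd.DataFrame([[1.0, 2, 3, 4], [4, 3, 2, 1]], index=["tf", "a"], columns=list("wxyz"))
        got = corr_mean(TFRecord(tf_id="tf"), _bicluster(["tf", "a"], "wxyz"), m)
        assert got == pytest.approx(1.0)  # only |corr(tf, a)| = 1


class TestProxMin:
    def _genes(self):
        return make_genes(
            [(f"g{i}", "chr1", 100 * i + 1, 100 * i + 50, "+", i) for i in range(10)]
            + [("p0", "plasmid", 1, 50, "+", 0)]
        )

    def test_member_tf_distance_zero(self):
        tf = TFRecord(tf_id="g3", replicon_id="chr1", gene_index=3)
        assert prox_min(tf, {"g3", "g7"}, self._genes()) == 0

    def test_adjacent_distance_one(self):
        tf = TFRecord(tf_id="g3", replicon_id="chr1", gene_index=3)
        assert prox_min(tf, {"g4"}, self._genes()) == 1

    def test_min_over_members(self):
        tf = TFRecord(tf_id="g0", replicon_id="chr1", gene_index=0)
        assert prox_min(tf, {"g5", "g2", "g9"}, self._genes()) == 2

    def test_other_replicon_undefined(self):
        tf = TFRecord(tf_id="g0", replicon_id="chr1", gene_index=0)
        assert prox_min(tf, {"p0"}, self._genes()) is None


class TestDbdScore:
    def _setup(self, rng):
        sites = ["TGACGTCATG"] * 8
        cluster_pssm = me.build_pssm(sites, motif_id="cl")
        lib = ReferenceMotifLibrary(
            entries=[
                (me.build_pssm(sites, motif_id="ref1"), "tf1", "Crp"),
                (me.build_pssm(["".join(rng.choice(list("ACGT"), 10)) for _ in range(8)], motif_id="ref2"), "tf2", "Crp"),
                (me.build_pssm(["".join(rng.choice(list("ACGT"), 10)) for _ in range(8)], motif_id="ref3"), "tf3", "LacI"),
            ]
        )
        qt = library_qvalues({"C0": cluster_pssm}, lib, n_shuffle=300, seed=0)
        return qt

    def test_identical_library_match_maximal(self, rng):
        qt = self._setup(rng)
        crp = dbd_score(TFRecord(tf_id="t", dbd_family="Crp"), "C0", qt)
        laci = dbd_score(TFRecord(tf_id="t", dbd_family="LacI"), "C0", qt)
        assert crp > laci

    def test_missing_family_undefined(self, rng):
        qt = self._setup(rng)
        assert dbd_score(TFRecord(tf_id="t", dbd_family="GntR"), "C0", qt) is None
        assert dbd_score(TFRecord(tf_id="t", dbd_family=""), "C0", qt) is None

    def test_min_q_selection_matches_brute_force(self, rng):
        qt = self._setup(rng)
        crp_rows = qt[(qt.cluster_id == "C0") & (qt.dbd_family == "Crp")]
        expect = -np.log10(crp_rows["q"].min())
        assert dbd_score(TFRecord(tf_id="t", dbd_family="Crp"), "C0", qt) == pytest.approx(expect)


class TestPhyloCorr:
    def _occurrence(self):
        genomes = ["t", "a", "b", "c"]
        groups = [f"G{i}" for i in range(6)]
        data = np.zeros((6, 4))
        data[:, 0] = [5, 4, 6, 0, 0, 3]  # target
        data[:, 1] = [5, 4, 6, 0, 0, 3]  # identical to target
        data[:, 2] = [4, 5, 5, 0, 1, 2]  # similar
        data[:, 3] = [0, 0, 1, 5, 4, 0]  # dissimilar
        return pd.DataFrame(data, index=groups, columns=genomes)

    def test_perfect_agreement(self):
        occ = self._occurrence()
        tf = TFRecord(tf_id="t", presence=pd.Series([1, 1, 1, 0], index=["t", "a", "b", "c"]))
        assert phylo_corr(tf, occ, "t") > 0.9

    def test_tf_everywhere_undefined(self):
        occ = self._occurrence()
        tf = TFRecord(tf_id="t", presence=pd.Series([1, 1, 1, 1], index=["t", "a", "b", "c"]))
        assert phylo_corr(tf, occ, "t") is None

    def test_hand_computation(self):
        occ = self._occurrence()
        pres = pd.Series([1, 0, 1, 0], index=["t", "a", "b", "c"])
        tf = TFRecord(tf_id="t", presence=pres)
        tvec = occ["t"].to_numpy()
        m = [np.corrcoef(occ[g], tvec)[0, 1] for g in ["t", "a", "b", "c"]]
        expect = np.corrcoef(m, pres.to_numpy())[0, 1]
        assert phylo_corr(tf, occ, "t") == pytest.approx(expect)

    def test_occurrence_vectors_from_hits(self):
        groups = [
            OrthologGroup("G0", {"t": ["t0"], "a": ["a0"]}),
            OrthologGroup("G1", {"t": ["t1"], "a": ["a1"]}),
        ]
        hits = {"t": {"t0": 1e-6}, "a": {"a1": 1e-3}}
        occ = motif_occurrence_vectors(hits, groups, ["t", "a"])
        assert occ.at["G0", "t"] == pytest.approx(6.0)
        assert occ.at["G1", "a"] == pytest.approx(3.0)
        assert occ.at["G1", "t"] == 0.0


class TestPermutationPvalue:
    def _null(self, values):
        return PermutationNull(criterion="corr", values=np.asarray(values, dtype=float), seed=0)

    def test_above_all_nulls_floor(self):
        null = self._null(np.linspace(0, 0.5, 1000))
        assert permutation_pvalue(0.9, null, "ge") == pytest.approx(1 / 1001)

    def test_below_all_nulls_is_one(self):
        null = self._null(np.linspace(0.5, 1.0, 1000))
        assert permutation_pvalue(0.1, null, "ge") == 1.0

    def test_median_observation_near_half(self):
        null = self._null(np.linspace(0, 1, 1000))
        p = permutation_pvalue(0.5, null, "ge")
        assert abs(p - 0.5) <= 2 / 1000

    def test_le_direction_for_distances(self):
        null = self._null(np.arange(1, 1001))
        assert permutation_pvalue(0.0, null, "le") == pytest.approx(1 / 1001)
        assert permutation_pvalue(2000.0, null, "le") == 1.0


class TestRScore:
    def test_all_tenths(self):
        assert r_score(0.1, 0.1, 0.1, 0.1) == pytest.approx(4.0)

    def test_single_informative_criterion(self):
        assert r_score(0.01, 1, 1, 1) == pytest.approx(2.0)

    def test_strictly_decreasing_in_each_p(self, rng):
        base = [0.2, 0.3, 0.4, 0.5]
        s0 = r_score(*base)
        for i in range(4):
            worse = list(base)
            worse[i] = min(1.0, base[i] * 2)
            assert r_score(*worse) < s0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            r_score(0.0, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            r_score(0.5, 0.5, 0.5, 1.5)

    def test_equals_sum_of_neglog_terms(self, rng):
        for _ in range(20):
            ps = rng.uniform(0.001, 1.0, size=4)
            expect = sum(-np.log10(p) for p in ps)
            assert r_score(*ps) == pytest.approx(expect, abs=1e-9)


def _score(tf_id, r, p_dbd=0.5, p_corr=0.5):
    # construct a TFClusterScore with a target r_score via p_prox
    p_prox = 10 ** (-(r - (-np.log10(p_dbd) - np.log10(p_corr))))
    p_prox = min(max(p_prox, 1e-300), 1.0)
    return TFClusterScore(
        tf_id=tf_id, cluster_id="C0", corr_mean=0.5, p_corr=p_corr,
        prox_min=1, p_prox=p_prox, dbd_score=1.0, p_dbd=p_dbd,
        phylo_corr=None, p_pc=1.0,
    )


class TestRanking:
    def test_single_tf_rank_one(self):
        out = rank_tfs_for_cluster([_score("a", 2.0)])
        assert out[0].tf_id == "a"

    def test_higher_score_first(self):
        out = rank_tfs_for_cluster([_score("a", 3.1), _score("b", 5.2)])
        assert [s.tf_id for s in out] == ["b", "a"]

    def test_tie_broken_by_p_dbd(self):
        a = TFClusterScore("a", "C0", 0.5, 0.1, 1, 0.1, 1.0, 0.5, None, 1.0)
        b = TFClusterScore("b", "C0", 0.5, 0.5, 1, 0.1, 1.0, 0.1, None, 1.0)
        assert a.r_score == pytest.approx(b.r_score)
        out = rank_tfs_for_cluster([a, b])
        assert out[0].tf_id == "b"  # lower p_dbd wins

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_tfs_for_cluster([])

    def test_neutralizing_a_criterion_never_raises_score(self, rng):
        for _ in range(10):
            ps = rng.uniform(0.01, 1.0, size=4)
            s = TFClusterScore("a", "C0", 0.5, ps[0], 1, ps[1], 1.0, ps[2], 0.5, ps[3])
            for field in ("p_corr", "p_prox", "p_dbd", "p_pc"):
                kwargs = dict(
                    tf_id="a", cluster_id="C0", corr_mean=0.5, p_corr=ps[0],
                    prox_min=1, p_prox=ps[1], dbd_score=1.0, p_dbd=ps[2],
                    phylo_corr=0.5, p_pc=ps[3],
                )
                kwargs[field] = 1.0
                assert TFClusterScore(**kwargs).r_score <= s.r_score + 1e-12


class TestBuildNulls:
    def _world(self, rng):
        r = np.random.default_rng(404)
        genes = make_genes([(f"g{i}", "chr1", 100 * i + 1, 100 * i + 50, "+", i) for i in range(60)])
        m = pd.DataFrame(
            r.normal(size=(60, 50)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"c{j}" for j in range(50)],
        )
        tfs = [TFRecord(tf_id=f"g{i}", dbd_family="Crp", replicon_id="chr1", gene_index=i) for i in range(12)]
        clusters = [
            Bicluster(
                cluster_id=f"C{k}",
                genes={f"g{i}" for i in r.choice(np.arange(20, 60), size=5, replace=False)},
                conditions={f"c{j}" for j in range(30)},
                mean_abs_pairwise_corr=0.5,
            )
            for k in range(10)
        ]
        return genes, m, tfs, clusters

    def test_reproducible_for_fixed_seed(self, rng):
        genes, m, tfs, clusters = self._world(rng)
        a = build_nulls("prox", tfs, clusters, genes=genes, n=200, seed=42)
        b = build_nulls("prox", tfs, clusters, genes=genes, n=200, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_corr_null_concentrates_near_analytic_mean(self, rng):
        """On pure-noise data the corr null mean approaches the expected
        |r| of independent Gaussians, sqrt(2/(pi*(n-1)))."""
        genes, m, tfs, clusters = self._world(rng)
        null = build_nulls("corr", tfs, clusters, matrix=m, n=400, seed=7)
        n_cond = 30
        expect = np.sqrt(2 / (np.pi * (n_cond - 1)))
        assert null.values.mean() == pytest.approx(expect, rel=0.15)

    def test_null_pvalues_approximately_uniform(self, rng):
        """Permutation p-values of true-null observations are uniform
        (KS test at alpha 0.01)."""
        genes, m, tfs, clusters = self._world(rng)
        null = build_nulls("corr", tfs, clusters, matrix=m, n=1000, seed=7)
        r = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            tf = tfs[r.integers(len(tfs))]
            cl = clusters[r.integers(len(clusters))]
            obs = corr_mean(tf, cl, m)
            ps.append(permutation_pvalue(obs, null, "ge"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
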