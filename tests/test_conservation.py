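"""Two-state phylo-HMM: tuning algebra, posteriors, Viterbi elements,
per-site scores, region-class score table."""

import numpy as np
import pandas as pd
import pytest

from cisrcne.conservation import (
    PhyloHMM,
    build_chains,
    _chain_llr,
    _forward_backward,
    _viterbi,
    call_most_cons,
    class_score_fractions,
    estimate_rho,
    hmm_from_tuning,
    per_site_score,
    posterior_conserved,
)
from cisrcne.io_formats import AlignmentBlock, GeneModel, GenomicInterval, MafRow
from cisrcne.phylo import PhyloTree, SubstitutionModel
from cisrcne.simulate import CladeSimConfig, simulate_clade


def _block(texts: dict[str, str], start: int = 0, chrom: str = "chr1"):
    width = len(next(iter(texts.values())))
    rows = {
        sp: MafRow(
            GenomicInterval(chrom, start, start + width - t.count("-")), "+", t, 10_000
        )
        for sp, t in texts.items()
    }
    return AlignmentBlock(ref_species="ref", rows=rows)


@pytest.fixture(scope="module")
def jc_hmm():
    tree = PhyloTree.from_newick("(ref:0.3,spB:0.3);")
    return hmm_from_tuning(0.2, 80, 0.3, SubstitutionModel.jc(), tree)


class TestTuning:
    def test_study_parameters(self, jc_hmm):
        assert jc_hmm.mu == pytest.approx(0.0125)
        assert jc_hmm.nu == pytest.approx(0.003125)

    def test_symmetric_gamma(self):
        tree = PhyloTree.from_newick("(ref:0.1,spB:0.1);")
        hmm = hmm_from_tuning(0.5, 10, 0.3, SubstitutionModel.jc(), tree)
        assert hmm.nu == pytest.approx(hmm.mu)

    def test_omega_one_exits_immediately(self):
        tree = PhyloTree.from_newick("(ref:0.1,spB:0.1);")
        hmm = hmm_from_tuning(0.2, 1, 0.3, SubstitutionModel.jc(), tree)
        assert hmm.mu == pytest.approx(1.0)

    @pytest.mark.parametrize("gamma", [0.0, 1.0, -0.1, 1.5])
    def test_gamma_out_of_range(self, gamma):
        tree = PhyloTree.from_newick("(ref:0.1,spB:0.1);")
        with pytest.raises(ValueError):
            hmm_from_tuning(gamma, 80, 0.3, SubstitutionModel.jc(), tree)


def enumerate_posteriors(llr, hmm):
    """Oracle: sum over all 2^n state paths (0 conserved, 1 neutral)."""
    n = len(llr)
    T = hmm.transition_matrix()
    init = hmm.initial_distribution()
    e = np.ones((n, 2))
    e[:, 0] = np.exp(llr)
    post = np.zeros((n, 2))
    total = 0.0
    for bits in range(2 ** n):
        path = [(bits >> k) & 1 for k in range(n)]
        p = init[path[0]] * e[0, path[0]]
        for t in range(1, n):
            p *= T[path[t - 1], path[t]] * e[t, path[t]]
        total += p
        for t in range(n):
            post[t, path[t]] += p
    return post[:, 0] / total


class TestForwardBackward:
    def test_degenerate_rho_gives_gamma(self):
        tree = PhyloTree.from_newick("(ref:0.3,spB:0.3);")
        hmm = hmm_from_tuning(0.2, 80, 1.0, SubstitutionModel.jc(), tree)
        block = _block({"ref": "ACGTACGTAC", "spB": "ACGTACGTAC"})
        post = posterior_conserved([block], hmm)
        for p in post["chr1"].values():
            assert p == pytest.approx(0.2, abs=1e-12)

    def test_matches_path_enumeration(self, jc_hmm):
        rng = np.random.default_rng(8)
        for _ in range(20):
            llr = rng.normal(0, 1.5, size=8)
            post, _ll = _forward_backward(llr, jc_hmm)
            want = enumerate_posteriors(llr, jc_hmm)
            assert np.allclose(post, want, atol=1e-10)

    def test_posteriors_in_unit_interval(self, jc_hmm):
        rng = np.random.default_rng(1)
        llr = rng.normal(0, 3, size=500)
        post, _ = _forward_backward(llr, jc_hmm)
        assert np.all((post >= 0) & (post <= 1))

    def test_empty_blocks(self, jc_hmm):
        assert posterior_conserved([], jc_hmm) == {}

    def test_planted_run_has_higher_posterior(self):
        clade = simulate_clade(
            CladeSimConfig(genome_length=40_000, n_genes=0, n_planted_cne=5,
                           rearrangements=(), dropout_frac=0.0, seed=21)
        )
        hmm = hmm_from_tuning(0.2, 80, 0.3, clade.model, clade.tree)
        post = posterior_conserved(clade.blocks, hmm)["chr1"]
        inside = [
            post[p] for iv in clade.truth.planted for p in range(iv.start, iv.end)
        ]
        planted = {
            p for iv in clade.truth.planted for p in range(iv.start, iv.end)
        }
        outside = [v for p, v in post.items() if p not in planted]
        assert np.mean(inside) > np.mean(outside) + 0.3


class TestViterbiElements:
    def test_identical_columns_give_one_spanning_element(self):
        tree = PhyloTree.from_newick(
            "((ref:0.2,spB:0.2):0.1,(spC:0.2,spD:0.2):0.1);"
        )
        hmm = hmm_from_tuning(0.2, 80, 0.3, SubstitutionModel.jc(), tree)
        text = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 3
        block = _block({sp: text for sp in ["ref", "spB", "spC", "spD"]})
        elements = call_most_cons([block], hmm)
        assert len(elements) == 1
        assert elements[0].interval == GenomicInterval("chr1", 0, len(text))
        assert elements[0].score > 0
        assert elements[0].mean_posterior > 0.9

    def test_degenerate_rho_calls_nothing(self):
        tree = PhyloTree.from_newick("(ref:0.3,spB:0.3);")
        hmm = hmm_from_tuning(0.2, 80, 1.0, SubstitutionModel.jc(), tree)
        block = _block({"ref": "ACGTACGTAC", "spB": "ACGTACGTAC"})
        elements = call_most_cons([block], hmm)
        assert elements == [] or all(abs(e.score) < 1e-9 for e in elements)

    def test_viterbi_beats_random_paths(self, jc_hmm):
        rng = np.random.default_rng(4)
        llr = rng.normal(0, 2, size=60)
        path = _viterbi(llr, jc_hmm)

        def log_prob(p):
            T = np.log(jc_hmm.transition_matrix())
            init = np.log(jc_hmm.initial_distribution())
            loge = np.zeros((len(llr), 2))
            loge[:, 0] = llr
            lp = init[p[0]] + loge[0, p[0]]
            for t in range(1, len(p)):
                lp += T[p[t - 1], p[t]] + loge[t, p[t]]
            return lp

        best = log_prob(path)
        for _ in range(1000):
            rand = rng.integers(0, 2, size=len(llr))
            assert log_prob(rand) <= best + 1e-9

    def test_deterministic_across_runs(self, small_clade):
        hmm = hmm_from_tuning(0.2, 80, 0.3, small_clade.model, small_clade.tree)
        a = call_most_cons(small_clade.blocks, hmm)
        b = call_most_cons(small_clade.blocks, hmm)
        assert a == b

    def test_chain_breaks_at_reference_gaps(self, jc_hmm):
        b1 = _block({"ref": "ACGT", "spB": "ACGT"}, start=0)
        b2 = _block({"ref": "ACGT", "spB": "ACGT"}, start=10)  # 6 bp gap
        chains = build_chains([b1, b2], jc_hmm.tree.leaf_names)
        assert len(chains) == 2

    def test_recovery_on_planted_elements(self):
        clade = simulate_clade(
            CladeSimConfig(genome_length=50_000, n_genes=0, n_planted_cne=10,
                           rearrangements=(), dropout_frac=0.0, seed=13)
        )
        hmm = hmm_from_tuning(0.2, 80, 0.3, clade.model, clade.tree)
        elements = call_most_cons(clade.blocks, hmm)

        def recip(a, b):
            ov = max(0, min(a.end, b.end) - max(a.start, b.start))
            return ov >= 0.5 * a.length and ov >= 0.5 * b.length

        planted = clade.truth.planted
        ivs = [e.interval for e in elements]
        recall = sum(any(recip(p, e) for e in ivs) for p in planted) / len(planted)
        precision = sum(any(recip(e, p) for p in planted) for e in ivs) / len(ivs)
        assert recall >= 0.8 and precision >= 0.8


class TestRhoEstimation:
    def test_rho_recovery_within_tolerance(self):
        clade = simulate_clade(
            CladeSimConfig(genome_length=50_000, n_genes=0, n_planted_cne=10,
                           rearrangements=(), dropout_frac=0.0, seed=13)
        )
        rho_hat = estimate_rho(clade.blocks, 0.2, 80, clade.model, clade.tree)
        assert rho_hat == pytest.approx(0.3, abs=0.1)


class TestPerSiteScore:
    def _invariant_blocks(self, total_length):
        t = total_length / 8.0
        tree = PhyloTree.from_newick(
            f"(((r1:{t},r2:{t}):{t},(r3:{t},r4:{t}):{t}):{t},"
            f"(r5:{t},r6:{t}):{t});".replace("r1", "ref")
        )
        text = "A" * 20
        block = _block({sp: text for sp in tree.leaf_names})
        return tree, block

    def test_invariant_column_scores_scale_with_tree_length(self):
        model = SubstitutionModel.jc()
        tree_long, block_long = self._invariant_blocks(2.0)
        tree_short, block_short = self._invariant_blocks(0.2)
        s_long = per_site_score([block_long], tree_long, model)["score"].iloc[0]
        s_short = per_site_score([block_short], tree_short, model)["score"].iloc[0]
        assert s_long > s_short > 0

    def test_near_boundary_score_is_small(self):
        # two species, tiny branch, identical bases: MLE hugs scale 1 region
        tree = PhyloTree.from_newick("(ref:0.005,spB:0.005);")
        block = _block({"ref": "A" * 5, "spB": "A" * 5})
        scores = per_site_score([block], tree, SubstitutionModel.jc())
        assert np.all(np.abs(scores["score"]) < 0.5)

    def test_acceleration_is_negative(self):
        tree = PhyloTree.from_newick("(ref:0.01,spB:0.01);")
        block = _block({"ref": "ACGTA", "spB": "CATGC"})  # all mismatches
        scores = per_site_score([block], tree, SubstitutionModel.jc())
        assert np.all(scores["score"] < 0)

    def test_uninformative_column_scores_zero(self):
        tree = PhyloTree.from_newick("(ref:0.1,spB:0.1);")
        block = _block({"ref": "ACG", "spB": "NNN"})  # spB all missing
        scores = per_site_score([block], tree, SubstitutionModel.jc())
        assert np.all(scores["score"] == 0.0)


class TestClassScoreFractions:
    def _gene(self, start, end, cds, strand="+"):
        return GeneModel(
            gene_id=f"g{start}",
            interval=GenomicInterval("chr1", start, end, strand),
            cds=[GenomicInterval("chr1", s, e, strand) for s, e in cds],
        )

    def test_constant_scores_give_top_percent(self):
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": range(12_000), "score": 1.0}
        )
        genes = [self._gene(5_000, 6_000, [(5_000, 6_000)])]
        table = class_score_fractions(scores, genes, top_percents=(10, 30))
        for _cls, row in table.iterrows():
            if row["n_sites"] > 0:
                # ties at a constant score: every site clears the cutoff
                assert row["top10"] == pytest.approx(1.0)

    def test_single_class_covering_everything(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": range(n), "score": rng.normal(size=n)}
        )
        genes = [self._gene(0, n, [(0, n)])]
        table = class_score_fractions(scores, genes, top_percents=(10, 60))
        assert table.loc["CDS", "top10"] == pytest.approx(0.10, abs=0.01)
        assert table.loc["CDS", "top60"] == pytest.approx(0.60, abs=0.01)

    def test_empty_class_is_nan_not_zero(self):
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": range(100), "score": 1.0}
        )
        genes = [self._gene(0, 100, [(0, 100)])]
        table = class_score_fractions(scores, genes, top_percents=(10,))
        assert np.isnan(table.loc["intron", "top10"])

    def test_cds_enrichment_detected(self):
        """Scores concentrated in CDS -> CDS top-10 fraction leads."""
        rng = np.random.default_rng(5)
        n = 20_000
        score = rng.normal(0, 1, size=n)
        score[8_000:9_000] += 3.0  # the CDS
        scores = pd.DataFrame({"chrom": "chr1", "pos": range(n), "score": score})
        genes = [self._gene(8_000, 9_000, [(8_000, 9_000)])]
        table = class_score_fractions(scores, genes, top_percents=(10,))
        cds_frac = table.loc["CDS", "top10"]
        up_frac = table.loc["upstream[-5000,-2000)", "top10"]
        assert cds_frac > 0.5 > up_frac

    def test_flanks_exclude_overlapping_gene_bodies(self):
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": range(10_000), "score": 1.0}
        )
        # two adjacent genes: the downstream window of g1 overlaps g2
        g1 = self._gene(2_000, 3_000, [(2_000, 3_000)])
        g2 = self._gene(3_050, 4_000, [(3_050, 4_000)])
        table = class_score_fractions(scores, [g1, g2], top_percents=(10,))
        # g1 downstream[0,100) has only 50 usable positions per gene side
        assert table.loc["downstream[0,100)", "n_sites"] <= 100 + 50
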