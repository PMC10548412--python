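"""Substitution models, pruning likelihoods, fitting, site classes."""

import numpy as np
import pytest

from cisrcne.io_formats import GenomicInterval
from cisrcne.phylo import (
    CODON12,
    FOURFOLD,
    MISSING,
    NONCODING,
    PhyloTree,
    SubstitutionModel,
    alignment_log_likelihoods,
    class_columns,
    column_log_likelihood,
    extract_site_classes,
    fit_model,
    load_model,
    path_distance,
    save_model,
)


def enumeration_log_likelihood(tree, model, column, scale=1.0):
    """Independent oracle: sum over all internal-state assignments."""
    internal = [i for i in tree.postorder if tree.children[i]]
    total = 0.0
    for assignment in np.ndindex(*(4,) * len(internal)):
        state = dict(zip(internal, assignment))
        prob = model.pi[state[tree.root]]
        for node in tree.postorder:
            if node == tree.root:
                continue
            P = model.transition_matrix(scale * tree.branch_lengths[node])
            parent_state = state[tree.parent[node]]
            if tree.children[node]:
                prob *= P[parent_state, state[node]]
            else:
                obs = column[node]
                if obs != MISSING:
                    prob *= P[parent_state, obs]
        total += prob
    return np.log(total)


def random_tree(rng, n_leaves):
    """Random rooted binary topology with random branch lengths."""
    names = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"{n}:{rng.uniform(0.01, 1.0):.4f}" for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 1.0):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return PhyloTree.from_newick(f"({nodes[0]},{nodes[1]});")


def random_model(rng):
    pi = rng.dirichlet([5, 5, 5, 5])
    rates = rng.uniform(0.3, 3.0, size=6)
    return SubstitutionModel.gtr(pi, rates)


class TestSubstitutionModel:
    def test_normalization(self):
        for m in (
            SubstitutionModel.jc(),
            SubstitutionModel.hky([0.3, 0.2, 0.2, 0.3], 2.0),
            SubstitutionModel.gtr([0.1, 0.4, 0.3, 0.2], [1, 2, 1, 1, 2, 1]),
        ):
            assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0)
            assert np.allclose(m.Q.sum(axis=1), 0.0)
            # detailed balance (reversibility)
            flux = m.pi[:, None] * m.Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_stationarity(self):
        m = SubstitutionModel.gtr([0.1, 0.4, 0.3, 0.2], [1, 2, 1, 1, 2, 1])
        P = m.transition_matrix(50.0)
        assert np.allclose(P, np.tile(m.pi, (4, 1)), atol=1e-8)


class TestColumnLikelihood:
    def test_zero_branch_identical_pair(self):
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        ll = column_log_likelihood(tree, SubstitutionModel.jc(), {"A": "A", "B": "A"})
        assert ll == pytest.approx(np.log(0.25))

    def test_long_branch_independence(self):
        tree = PhyloTree.from_newick("(A:40.0,B:40.0);")
        ll = column_log_likelihood(tree, SubstitutionModel.jc(), {"A": "A", "B": "C"})
        assert ll == pytest.approx(np.log(1 / 16), abs=1e-6)

    def test_unknown_species_raises(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(KeyError):
            column_log_likelihood(tree, SubstitutionModel.jc(), {"Z": "A"})

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_leaves = int(rng.integers(2, 6))
            tree = random_tree(rng, n_leaves)
            model = random_model(rng)
            column = rng.integers(-1, 4, size=n_leaves)
            scale = float(rng.uniform(0.1, 2.0))
            got = alignment_log_likelihoods(tree, model, column[None, :], scale)[0]
            want = enumeration_log_likelihood(tree, model, column, scale)
            assert got == pytest.approx(want, abs=1e-10)

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, 5)
        model = random_model(rng)
        col = {name: "ACGTA"[i] for i, name in enumerate(tree.leaf_names)}
        ll = column_log_likelihood(tree, model, col)
        items = list(col.items())[::-1]
        assert column_log_likelihood(tree, model, dict(items)) == pytest.approx(ll)

    def test_all_missing_column_is_neutral(self):
        tree = PhyloTree.from_newick("(A:0.2,B:0.3);")
        ll = alignment_log_likelihoods(
            tree, SubstitutionModel.jc(), np.array([[MISSING, MISSING]])
        )[0]
        assert ll == pytest.approx(0.0)


def _simulate_columns(tree, model, n, rng):
    seqs = {tree.root: rng.choice(4, size=n, p=model.pi)}
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        P = model.transition_matrix(tree.branch_lengths[node])
        parent = seqs[tree.parent[node]]
        child = np.empty(n, dtype=np.int64)
        for b in range(4):
            idx = np.flatnonzero(parent == b)
            if len(idx):
                child[idx] = rng.choice(4, size=len(idx), p=P[b])
        seqs[node] = child
    return np.stack([seqs[tree.leaf_index[x]] for x in tree.leaf_names], axis=1)


class TestFitModel:
    def test_jc_branch_length_recovery(self):
        t_true = 0.15
        tree = PhyloTree.from_newick(
            f"((A:{t_true},B:{t_true}):{t_true},(C:{t_true},D:{t_true}):{t_true});"
        )
        rng = np.random.default_rng(5)
        cols = _simulate_columns(tree, SubstitutionModel.jc(), 10_000, rng)
        _model, fitted = fit_model(cols, tree, family="JC")
        for i in tree.free_branches():
            assert fitted.branch_lengths[i] == pytest.approx(t_true, rel=0.15)

    def test_two_species_closed_form(self):
        tree = PhyloTree.from_newick("(A:0.05,B:0.05);")
        rng = np.random.default_rng(9)
        anc = rng.integers(0, 4, 5000)
        P = SubstitutionModel.jc().transition_matrix(0.2)
        other = np.array([rng.choice(4, p=P[b]) for b in anc])
        cols = np.stack([anc, other], axis=1)
        p_mismatch = float((cols[:, 0] != cols[:, 1]).mean())
        jc_distance = -0.75 * np.log(1 - 4 * p_mismatch / 3)
        _m, fitted = fit_model(cols, tree, family="JC")
        assert fitted.total_length() == pytest.approx(jc_distance, abs=1e-4)

    def test_identical_columns_drive_lengths_to_zero(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        cols = np.zeros((200, 3), dtype=np.int64)  # all 'A'
        _m, fitted = fit_model(cols, tree, family="JC")
        assert fitted.total_length() < 1e-4

    def test_fit_beats_truth(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 4)
        model = SubstitutionModel.jc()
        cols = _simulate_columns(tree, model, 2000, rng)
        fitted_m, fitted_t = fit_model(cols, tree, family="JC")
        ll_fit = alignment_log_likelihoods(fitted_t, fitted_m, cols).sum()
        ll_true = alignment_log_likelihoods(tree, model, cols).sum()
        assert ll_fit >= ll_true - 1e-6

    def test_too_few_columns(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="50"):
            fit_model(np.zeros((10, 2), dtype=np.int64), tree)


class TestPathDistance:
    def test_identity_and_simple_sum(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        assert path_distance(tree, "A", "A") == 0.0
        assert path_distance(tree, "A", "B") == pytest.approx(0.2)

    def test_hand_sum_on_simulator_tree(self, small_clade):
        tree = small_clade.tree
        # caterpillar: ((((ref:.05,spB:.05):.05,spC:.08):.06,spD:.12):.08,spE:.20)
        assert path_distance(tree, "ref", "spB") == pytest.approx(0.10)
        assert path_distance(tree, "ref", "spC") == pytest.approx(0.18)
        assert path_distance(tree, "ref", "spD") == pytest.approx(0.28)
        assert path_distance(tree, "ref", "spE") == pytest.approx(0.44)

    def test_unknown_leaf(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(KeyError):
            path_distance(tree, "A", "Z")


class TestSiteClasses:
    def _blocks_for(self, seq):
        from cisrcne.io_formats import AlignmentBlock, MafRow

        return [
            AlignmentBlock(
                ref_species="ref",
                rows={
                    "ref": MafRow(
                        GenomicInterval("chr1", 0, len(seq)), "+", seq, len(seq)
                    )
                },
            )
        ]

    def _gene(self, gid, start, end, cds, strand="+"):
        from cisrcne.io_formats import GeneModel

        return GeneModel(
            gene_id=gid,
            interval=GenomicInterval("chr1", start, end, strand),
            cds=[GenomicInterval("chr1", s, e, strand) for s, e in cds],
        )

    def test_fourfold_glycine_third_position(self):
        # GGA GGC: glycine is GGN -> both third positions are four-fold
        blocks = self._blocks_for("GGAGGC")
        genes = [self._gene("g", 0, 6, [(0, 6)])]
        classes = extract_site_classes(blocks, genes)
        assert classes.label_of("chr1", 2) == FOURFOLD
        assert classes.label_of("chr1", 5) == FOURFOLD
        assert classes.label_of("chr1", 0) == CODON12
        assert classes.label_of("chr1", 1) == CODON12

    def test_atg_has_no_fourfold(self):
        blocks = self._blocks_for("ATGTAA")
        genes = [self._gene("g", 0, 6, [(0, 6)])]
        classes = extract_site_classes(blocks, genes)
        assert classes.label_of("chr1", 0) == CODON12
        assert classes.label_of("chr1", 1) == CODON12
        assert classes.label_of("chr1", 2) != FOURFOLD

    def test_minus_strand_codons(self):
        # reverse complement of GGA GGT is ACC TCC; gene on '-' covering it
        blocks = self._blocks_for("ACCTCC")
        genes = [self._gene("g", 0, 6, [(0, 6)], strand="-")]
        classes = extract_site_classes(blocks, genes)
        # transcript codons read right-to-left complemented: GGA, GGT
        assert classes.label_of("chr1", 3) == FOURFOLD  # 3rd pos of GGA
        assert classes.label_of("chr1", 0) == FOURFOLD  # 3rd pos of GGT

    def test_noncoding_and_hand_count_on_toy(self):
        # two genes in a 40 bp stretch, hand-countable
        seq = "GGAGGC" + "T" * 10 + "GGTGGG" + "A" * 18
        blocks = self._blocks_for(seq)
        genes = [
            self._gene("g1", 0, 6, [(0, 6)]),
            self._gene("g2", 16, 22, [(16, 22)]),
        ]
        classes = extract_site_classes(blocks, genes)
        counts = classes.counts()
        assert counts[FOURFOLD] == 4      # 4 glycine third positions
        assert counts[CODON12] == 8
        assert counts[NONCODING] == len(seq) - 12
        cols = class_columns(blocks, classes, FOURFOLD, ["ref"])
        assert cols.shape == (4, 1)

    def test_cds_not_multiple_of_three_skipped(self):
        blocks = self._blocks_for("GGAGG")
        genes = [self._gene("g", 0, 5, [(0, 5)])]
        with pytest.warns(UserWarning, match="divisible by 3"):
            classes = extract_site_classes(blocks, genes)
        assert classes.skipped_genes == ["g"]

    def test_simulator_fourfold_fraction(self, small_clade):
        """Simulator truth: third positions of 4-fold codons recovered."""
        classes = extract_site_classes(small_clade.blocks, small_clade.ref_genes)
        counts = classes.counts()
        # every gene contributes ~ cds_len/3 third positions, ~half 4-fold
        total_cds = sum(g.cds_length() for g in small_clade.ref_genes)
        assert 0 < counts[FOURFOLD] < total_cds / 3
        assert counts[CODON12] == pytest.approx(2 * total_cds / 3, rel=0.01)


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        m = SubstitutionModel.hky([0.3, 0.2, 0.2, 0.3], 2.5)
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        path = tmp_path / "model.txt"
        save_model(m, tree, str(path), rho=0.3)
        m2, t2, rho = load_model(str(path))
        assert np.allclose(m2.Q, m.Q) and np.allclose(m2.pi, m.pi)
        assert rho == pytest.approx(0.3)
        assert t2.leaf_names == tree.leaf_names
        assert np.allclose(
            sorted(t2.branch_lengths), sorted(tree.branch_lengths)
        )
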