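import math

import numpy as np
import pytest

from planctotaxa import seqmodels as sq
from planctotaxa import synthetic_data as sim
from planctotaxa import trees as tr

from helpers import brute_force_loglik

JC = sq.SubstitutionModel.jc69()
GTR_G = sq.SubstitutionModel.gtr(
    (1.0, 2.5, 0.8, 1.2, 3.0, 1.0), (0.31, 0.19, 0.27, 0.23), gamma_shape=0.6)


class TestAlignmentIO:
    def test_read_uppercases(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacgtacgtac\n>s2\nACGTACGTAC\n")
        aln = sq.read_fasta_alignment(p)
        assert aln.length == 10
        assert aln.sequences["s1"] == "ACGTACGTAC"

    def test_ragged_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGT\n>s2\nACGTA\n")
        with pytest.raises(sq.AlignmentError, match="ragged"):
            sq.read_fasta_alignment(p)

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(sq.AlignmentError):
            sq.read_fasta_alignment(p)


class TestRYRecoding:
    def test_basic_mapping(self):
        aln = sq.ry_recode(sq.Alignment({"s": "ACGT"}))
        assert aln.sequences["s"] == "RYRY"
        assert aln.alphabet == "ry"

    def test_gaps_kept_ambiguity_dropped(self):
        aln = sq.ry_recode(sq.Alignment({"s": "A-NWS"}))
        # W (A/T) and S (C/G) straddle the purine/pyrimidine split
        assert aln.sequences["s"] == "R-???"

    def test_within_class_ambiguity_resolves(self):
        aln = sq.ry_recode(sq.Alignment({"s": "RYKM"}))
        # K (G/T) and M (A/C) straddle; R and Y stay
        assert aln.sequences["s"] == "RY??"

    def test_double_recode_rejected(self):
        aln = sq.ry_recode(sq.Alignment({"s": "ACGT"}))
        with pytest.raises(sq.AlignmentError, match="already"):
            sq.ry_recode(aln)


class TestGammaRates:
    def test_rates_average_to_one(self):
        for shape in (0.2, 0.7, 1.0, 5.0):
            rates = sq.gamma_category_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(rates) > 0).all()

    def test_single_category_is_flat(self):
        assert sq.gamma_category_rates(0.5, 1).tolist() == [1.0]


class TestTransitionProbabilities:
    @pytest.mark.parametrize("model", [JC, GTR_G], ids=["jc", "gtr"])
    def test_zero_time_is_identity(self, model):
        np.testing.assert_allclose(
            sq.transition_probabilities(model, 0.0), np.eye(4), atol=1e-12)

    def test_jc_closed_form(self):
        P = sq.transition_probabilities(JC, 0.1)
        diag = 0.25 + 0.75 * math.exp(-4 * 0.1 / 3)
        np.testing.assert_allclose(np.diag(P), diag, atol=1e-12)

    @pytest.mark.parametrize("model", [JC, GTR_G], ids=["jc", "gtr"])
    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0])
    def test_rows_stochastic_and_reversible(self, model, t):
        P = sq.transition_probabilities(model, t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        pi = np.asarray(model.base_frequencies)
        np.testing.assert_allclose(pi[:, None] * P, (pi[:, None] * P).T,
                                   atol=1e-10)

    def test_long_time_reaches_stationarity(self):
        P = sq.transition_probabilities(GTR_G, 50.0)
        for row in P:
            np.testing.assert_allclose(row, GTR_G.base_frequencies, atol=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sq.transition_probabilities(JC, -0.1)


class TestSiteLogLikelihoods:
    def test_identical_pair_zero_branch(self):
        aln = sq.Alignment({"A": "ACGT", "B": "ACGT"})
        tree = tr.parse_newick("(A:0,B:0);")
        sll = sq.site_log_likelihoods(aln, tree, JC)
        np.testing.assert_allclose(sll.per_site, math.log(0.25), atol=1e-12)

    def test_two_taxon_jc_closed_form(self):
        aln = sq.Alignment({"A": "ACGTAC", "B": "ACGTAT"})
        tree = tr.parse_newick("(A:0.07,B:0.13);")
        t = 0.2
        same = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
        diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3))
        expected = 5 * math.log(same) + math.log(diff)
        got = sq.log_likelihood(aln, tree, JC)
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("model", [JC, GTR_G], ids=["jc", "gtr+g"])
    def test_matches_state_enumeration_on_quartet(self, model):
        tree = tr.parse_newick("((A:0.11,B:0.23):0.08,(C:0.31,D:0.12):0.05);")
        aln = sim.simulate_alignment(tree, JC, 8, seed=5)
        got = sq.log_likelihood(aln, tree, model)
        expected = brute_force_loglik(aln, tree, model)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_ambiguity_codes_as_partial_information(self):
        # an N tip contributes no information: likelihood equals the
        # single-sequence stationary probability
        aln = sq.Alignment({"A": "A", "B": "N"})
        tree = tr.parse_newick("(A:0.4,B:0.4);")
        assert sq.log_likelihood(aln, tree, JC) == pytest.approx(
            math.log(0.25), abs=1e-12)

    def test_label_mismatch_lists_difference(self):
        aln = sq.Alignment({"A": "AC", "X": "AC"})
        tree = tr.parse_newick("(A:1,B:1);")
        with pytest.raises(tr.TreeError, match="B.*X|X.*B"):
            sq.site_log_likelihoods(aln, tree, JC)

    def test_total_is_sum_of_per_site(self):
        tree = tr.parse_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        aln = sim.simulate_alignment(tree, JC, 40, seed=1)
        sll = sq.site_log_likelihoods(aln, tree, JC)
        assert sll.total == pytest.approx(sll.per_site.sum(), abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_pulley_principle(self, seed):
        # reversible models: the likelihood does not depend on root placement
        tree = sim.simulate_tree(6, seed=seed, rate_sigma=0.4)
        aln = sim.simulate_alignment(tree, GTR_G, 30, seed=seed + 100)
        base = sq.log_likelihood(aln, tree, GTR_G)
        for tip in tree.tip_labels():
            rerooted = tr.outgroup_root(tree, tip)
            assert sq.log_likelihood(aln, rerooted, GTR_G) == pytest.approx(
                base, abs=1e-8)

    def test_ry_likelihood_runs(self):
        aln = sq.ry_recode(sq.Alignment({"A": "ACGTAC", "B": "AAGTAT"}))
        tree = tr.parse_newick("(A:0.1,B:0.1);")
        model = sq.SubstitutionModel.ry_symmetric()
        assert sq.log_likelihood(aln, tree, model) < 0


class TestBranchLengthOptimization:
    def test_recovers_jc_distance(self, rng):
        n, p = 3000, 0.3
        a = rng.integers(4, size=n)
        b = a.copy()
        hit = rng.random(n) < p
        b[hit] = (a[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        DNA = np.array(list("ACGT"))
        aln = sq.Alignment({"A": "".join(DNA[a]), "B": "".join(DNA[b])})
        tree = tr.parse_newick("(A:0.1,B:0.1);")
        opt = sq.optimize_branch_lengths(tree, aln, JC)
        total = sum(nd.length for nd in opt.postorder() if nd is not opt.root)
        p_hat = float((a != b).mean())
        expected = -0.75 * math.log(1 - 4 * p_hat / 3)
        assert total == pytest.approx(expected, rel=1e-4)

    def test_identical_sequences_shrink_branches(self):
        aln = sq.Alignment({"A": "ACGT" * 25, "B": "ACGT" * 25})
        tree = tr.parse_newick("(A:0.5,B:0.5);")
        opt = sq.optimize_branch_lengths(tree, aln, JC)
        for node in opt.postorder():
            if node is not opt.root:
                assert node.length < 1e-4

    def test_loglik_never_decreases(self):
        tree = sim.simulate_tree(5, seed=3)
        aln = sim.simulate_alignment(tree, JC, 200, seed=4)
        start = tree.copy()
        for node in start.postorder():
            if node is not start.root:
                node.length = 0.3
        before = sq.log_likelihood(aln, start, JC)
        after = sq.log_likelihood(aln, sq.optimize_branch_lengths(
            start, aln, JC, tol=1e-4, max_cycles=5, xatol=1e-5), JC)
        assert after >= before

    def test_recovery_on_simulated_tree(self):
        true = sim.simulate_tree(5, seed=7)
        for node in true.postorder():
            if node.length is not None:
                node.length = max(node.length * 0.3, 0.02)
        aln = sim.simulate_alignment(true, JC, 10000, seed=8)
        start = true.copy()
        for node in start.postorder():
            if node is not start.root:
                node.length = 0.1
        opt = sq.optimize_branch_lengths(start, aln, JC, tol=1e-4)
        # the two root-adjacent branches are only jointly identifiable
        # (pulley principle), so compare their sum and every other branch
        for got_node, want_node in zip(opt.postorder(), true.postorder()):
            if got_node is opt.root or got_node.parent is opt.root:
                continue
            assert got_node.length == pytest.approx(
                want_node.length, rel=0.10, abs=0.01)
        got_root = sum(c.length for c in opt.root.children)
        want_root = sum(c.length for c in true.root.children)
        assert got_root == pytest.approx(want_root, rel=0.10, abs=0.02)


class TestModelConfig:
    def test_gtr_gamma_round_trip(self, tmp_path):
        p = tmp_path / "model.cfg"
        p.write_text(
            "model=GTR\ngamma_shape=0.5\ngamma_categories=4\n"
            "base_frequencies=0.3,0.2,0.3,0.2\n"
            "exchangeabilities=1,2,1,1,4,1\n")
        model = sq.read_model_config(p)
        assert model.gamma_shape == 0.5
        assert model.base_frequencies == (0.3, 0.2, 0.3, 0.2)
        assert model.exchangeabilities == (1, 2, 1, 1, 4, 1)

    def test_jc_default(self, tmp_path):
        p = tmp_path / "model.cfg"
        p.write_text("model=JC\n")
        model = sq.read_model_config(p)
        assert model.base_frequencies == (0.25,) * 4
        assert model.gamma_shape is None

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "model.cfg"
        p.write_text("model=JC\nbogus=1\n")
        with pytest.raises(ValueError, match="bogus"):
            sq.read_model_config(p)
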