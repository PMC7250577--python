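import itertools
import math

import dendropy
import numpy as np
import pytest

from chimeradx import phylo, simulate as sim
from chimeradx.seqcore import Alignment
from chimeradx.substitution import AMINO_ACIDS, lg_model, poisson_model


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def oracle_lnl(tree, alignment, model):
    """Exhaustive summation over all internal-node state assignments."""
    tree = tree.clone(depth=1)
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    rows = dict(alignment.rows)
    pi = model.equilibrium_freqs
    rates = model.category_rates
    total = 0.0
    for site in range(alignment.n_columns):
        site_lik = 0.0
        for rate in rates:
            pmat = {id(nd): model.transition_matrix(
                max(nd.edge.length or 0.0, 0.0) * rate) for nd in nodes}
            lik = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                state = {id(nd): s for nd, s in zip(internals, assign)}
                for nd in nodes:
                    if nd.is_leaf():
                        ch = rows[nd.taxon.label][site]
                        state[id(nd)] = None if ch in "-X" else \
                            AMINO_ACIDS.index(ch)
                prob = pi[state[id(tree.seed_node)]]
                for nd in nodes:
                    if nd.parent_node is None:
                        continue
                    s_child = state[id(nd)]
                    s_parent = state[id(nd.parent_node)]
                    if s_child is None:
                        continue  # missing: sum over child states = 1
                    prob *= pmat[id(nd)][s_parent, s_child]
                lik += prob
            site_lik += lik / len(rates)
        total += math.log(site_lik)
    return total


class TestLogLikelihoodClosedForms:
    def test_identical_tips_zero_branches(self, poisson):
        tree = _tree("(A:0.0,B:0.0);")
        aln = Alignment([("A", "ACDEF"), ("B", "ACDEF")])
        assert phylo.log_likelihood(tree, aln, poisson) == pytest.approx(
            5 * math.log(1 / 20), abs=1e-9)

    def test_two_taxon_single_differing_site(self, poisson):
        """lnL = ln[ pi_i * P_ij(t) ] with the equal-rates transition
        P_ij(t) = (1/20)(1 - exp(-(20/19) t)) for i != j."""
        t = 0.3
        tree = _tree(f"(A:{t / 2},B:{t / 2});")
        aln = Alignment([("A", "A"), ("B", "R")])
        expected = math.log((1 / 20) * (1 / 20) * (1 - math.exp(-(20 / 19) * t)))
        assert phylo.log_likelihood(tree, aln, poisson) == pytest.approx(
            expected, abs=1e-10)

    def test_tip_row_mismatch_rejected(self, poisson):
        tree = _tree("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            phylo.log_likelihood(tree, Alignment([("A", "AC"), ("C", "AC")]),
                                 poisson)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("model_name", ["poisson", "lg_gamma"])
    @pytest.mark.parametrize("newick,ntips", [
        ("(A:0.2,B:0.7);", 2),
        ("((A:0.1,B:0.3):0.2,C:0.5);", 3),
        ("(((A:0.1,B:0.2):0.15,C:0.3):0.1,(D:0.25,E:0.05):0.2);", 5),
    ])
    def test_pruning_matches_exhaustive_summation(self, model_name, newick,
                                                  ntips):
        model = poisson_model() if model_name == "poisson" else \
            lg_model(gamma_shape=0.7, n_rate_categories=2)
        tree = _tree(newick)
        rng = np.random.default_rng(ntips)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rows = []
        for lab in labels:
            chars = rng.choice(list(AMINO_ACIDS), size=6)
            if lab == "B":
                chars[2] = "-"  # missing data handled as all-ones partial
            rows.append((lab, "".join(chars)))
        aln = Alignment(rows)
        got = phylo.log_likelihood(tree, aln, model)
        want = oracle_lnl(tree, aln, model)
        assert got == pytest.approx(want, rel=1e-8)

    def test_invariance_under_rerooting(self, lg):
        tree = _tree("(((A:0.1,B:0.2):0.15,C:0.3):0.1,(D:0.25,E:0.05):0.2);")
        aln = sim.evolve_alignment(tree, 40, lg, seed=3)
        base = phylo.log_likelihood(tree, aln, lg)
        for leaf_label in ("A", "D"):
            rerooted = tree.clone(depth=1)
            node = rerooted.find_node_with_taxon_label(leaf_label)
            half = node.edge.length / 2
            rerooted.reroot_at_edge(node.edge, length1=half, length2=half,
                                    update_bipartitions=False)
            assert phylo.log_likelihood(rerooted, aln, lg) == pytest.approx(
                base, rel=1e-9)


class TestMLTreeSearch:
    def test_three_taxa_unique_topology(self, poisson):
        tree = _tree("((A:0.1,B:0.2):0.0,C:0.3);")
        aln = sim.evolve_alignment(tree, 200, poisson, seed=1)
        best = phylo.ml_tree_search(aln, poisson, seed=0)
        assert len(best.leaf_nodes()) == 3
        assert best.log_likelihood == pytest.approx(
            phylo.log_likelihood(best, aln, poisson), rel=1e-9)

    def test_four_taxa_recovers_topology_vs_exhaustive_scan(self, poisson):
        true = _tree("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);")
        aln = sim.evolve_alignment(true, 500, poisson, seed=2)
        best = phylo.ml_tree_search(aln, poisson, seed=0)
        # oracle: optimize branch lengths on each of the 3 topologies
        topologies = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        scores = []
        for nwk in topologies:
            ut = phylo.UTree.from_dendropy(_tree(nwk), require_blens=False)
            engine = phylo._Engine(poisson, aln, ut.labels)
            scores.append(engine.optimize_branches(ut, n_sweeps=10))
        assert np.argmax(scores) == 0
        assert phylo.rf_distance(best, true) == 0
        assert best.log_likelihood == pytest.approx(max(scores), abs=0.05)

    def test_branch_optimizer_never_decreases_lnl(self, poisson):
        rng = np.random.default_rng(8)
        for rep in range(5):
            true = sim.simulate_yule_tree(6, 1.0, seed=rep)
            sim.scale_tree_height(true, 0.5)
            aln = sim.evolve_alignment(true, 120, poisson, seed=rep)
            ut = phylo.UTree.from_dendropy(true)
            # perturb branch lengths
            for (u, v) in ut.edges():
                ut.set_length(u, v, float(rng.uniform(0.01, 1.0)))
            engine = phylo._Engine(poisson, aln, ut.labels)
            before = engine.lnl(ut)
            after = engine.optimize_branches(ut)
            assert after >= before - 1e-6

    def test_too_few_sequences_rejected(self, poisson):
        with pytest.raises(ValueError):
            phylo.ml_tree_search(Alignment([("A", "ACD"), ("B", "ACD")]),
                                 poisson)

    def test_six_taxon_topology_recovery(self, poisson):
        """Trees inferred from >= 500-site alignments recover the generating
        6-taxon topology in at least 90% of 20 seeded runs.  Generating
        trees keep every internal branch resolvable (>= 0.03 substitutions
        per site): no method can recover a zero-length split."""
        hits = 0
        for seed in range(20):
            true = sim.simulate_yule_tree(6, 1.0, seed=1000 + seed)
            sim.scale_tree_height(true, 0.6)
            for edge in true.preorder_edge_iter():
                if (edge.head_node.parent_node is not None
                        and not edge.head_node.is_leaf()
                        and edge.length < 0.03):
                    edge.length = 0.03
            aln = sim.evolve_alignment(true, 500, poisson, seed=seed)
            best = phylo.ml_tree_search(aln, poisson, seed=seed)
            hits += phylo.rf_distance(best, true) == 0
        assert hits >= 18


_RECOVERY = []


class TestConstraints:
    def _setup(self, poisson):
        true = _tree("(((A:0.1,B:0.1):0.15,C:0.2):0.1,(D:0.1,E:0.15):0.1,F:0.3);")
        aln = sim.evolve_alignment(true, 300, poisson, seed=5)
        return true, aln

    def test_fully_resolved_constraint_fixes_topology(self, poisson):
        true, aln = self._setup(poisson)
        constraint = phylo.ConstraintTree(true)
        out = phylo.constrained_ml_search(aln, poisson, constraint, seed=0)
        assert phylo.rf_distance(out, true) == 0

    def test_star_constraint_equals_unconstrained(self, poisson):
        _, aln = self._setup(poisson)
        star = phylo.star_constraint(list("ABCDEF"))
        free = phylo.ml_tree_search(aln, poisson, seed=1)
        constrained = phylo.constrained_ml_search(aln, poisson, star, seed=1)
        assert constrained.log_likelihood == pytest.approx(
            free.log_likelihood, abs=1e-6)

    def test_constrained_never_beats_unconstrained(self, poisson):
        _, aln = self._setup(poisson)
        free = phylo.ml_tree_search(aln, poisson, seed=1)
        for groups in ({"g": ["A", "D"]}, {"g": ["C", "F"]},
                       {"g1": ["A", "B", "C"], "g2": ["D", "E", "F"]}):
            con = phylo.monophyly_constraint(groups, list("ABCDEF"))
            fit = phylo.constrained_ml_search(aln, poisson, con, seed=1)
            assert fit.log_likelihood <= free.log_likelihood + 1e-6
            assert con.satisfied_by(phylo.UTree.from_dendropy(fit))

    def test_contradictory_constraint_rejected(self):
        nwk = "((A,B),(A,C));"  # duplicate tip label -> invalid
        with pytest.raises(Exception):
            phylo.ConstraintTree(_tree(nwk))


class TestSOWH:
    def test_compliant_observed_tree_gives_p_near_one(self, poisson):
        true = _tree("(((A:0.1,B:0.1):0.15,C:0.2):0.1,(D:0.1,E:0.15):0.1,F:0.3);")
        aln = sim.evolve_alignment(true, 300, poisson, seed=5)
        con = phylo.monophyly_constraint({"g": ["A", "B", "C"]}, list("ABCDEF"))
        res = phylo.sowh_test(aln, poisson, con, n_sims=30, seed=2)
        assert res.observed_delta_lnl <= 0.5
        assert res.p_value > 0.5
        assert res.n_sims == 30
        assert len(res.null_deltas) == 30
        # +1/+1 estimator bounds
        assert 1 / 31 <= res.p_value <= 1.0

    def test_violated_constraint_rejected(self, poisson):
        true = _tree("(((A:0.02,B:0.02):0.4,C:0.4):0.2,(D:0.02,E:0.4):0.02,F:0.4);")
        aln = sim.evolve_alignment(true, 400, poisson, seed=9)
        # force A with D: strongly contradicted by the data
        con = phylo.monophyly_constraint({"g": ["A", "D"]}, list("ABCDEF"))
        res = phylo.sowh_test(aln, poisson, con, n_sims=30, seed=3)
        assert res.observed_delta_lnl > 5
        assert res.p_value <= 0.05


class TestTreeComparison:
    def test_rf_identical_and_symmetry_and_bound(self):
        t1 = _tree("(((A,B),C),(D,E),F);")
        t2 = _tree("(((A,C),B),(D,F),E);")
        assert phylo.rf_distance(t1, t1.clone(depth=1)) == 0
        d12 = phylo.rf_distance(t1, t2)
        assert d12 == phylo.rf_distance(t2, t1)
        assert 0 < d12 <= 2 * (6 - 3)

    def test_rf_against_dendropy(self):
        rng = np.random.default_rng(0)
        for rep in range(5):
            t1 = sim.simulate_yule_tree(7, 1.0, seed=rep)
            t2 = sim.simulate_yule_tree(7, 1.0, seed=100 + rep)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            d1.deroot()
            d2.deroot()
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            want = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert phylo.rf_distance(t1, t2) == want

    def test_tip_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phylo.rf_distance(_tree("((A,B),(C,D));"), _tree("((A,B),(C,E));"))

    def test_jaccard_identical_trees_all_ones(self):
        t = _tree("(((A,B),C),(D,E));")
        scores = phylo.jaccard_tree_similarity(t, t.clone(depth=1))
        assert scores
        assert all(v == 1.0 for v in scores.values())

    def test_jaccard_nni_neighbor_matches_direct_computation(self):
        t1 = _tree("(((A,B),C),(D,E));")
        t2 = _tree("(((A,C),B),(D,E));")
        scores = phylo.jaccard_tree_similarity(t1, t2)
        clades2 = [frozenset(x) for x in
                   [{"A", "C"}, {"A", "B", "C"}, {"D", "E"},
                    {"A", "B", "C", "D", "E"}]]
        for clade, got in scores.items():
            want = max(len(clade & c) / len(clade | c) for c in clades2)
            assert got == pytest.approx(want)
        assert all(0 < v <= 1 for v in scores.values())

    def test_disjoint_tip_sets_rejected(self):
        with pytest.raises(ValueError):
            phylo.jaccard_tree_similarity(_tree("((A,B),C);"),
                                          _tree("((X,Y),Z);"))


class TestBootstrap:
    def test_unanimous_signal_gives_full_support(self, poisson):
        # every site supports AB|CD: build a 4-taxon alignment where A,B
        # share one residue and C,D another, per column
        rng = np.random.default_rng(4)
        cols_ab = rng.choice(list(AMINO_ACIDS), size=120)
        cols_cd = rng.choice(list(AMINO_ACIDS), size=120)
        keep = cols_ab != cols_cd
        aln = Alignment([
            ("A", "".join(cols_ab[keep])), ("B", "".join(cols_ab[keep])),
            ("C", "".join(cols_cd[keep])), ("D", "".join(cols_cd[keep]))])
        out = phylo.bootstrap_support(aln, poisson, n_reps=20, seed=0)
        supports = [float(nd.label) for nd in out.postorder_node_iter()
                    if nd.label and not nd.is_leaf()]
        assert supports and all(s == 100.0 for s in supports)

    def test_support_values_bounded_and_deterministic(self, poisson):
        tree = _tree("(((A:0.1,B:0.1):0.1,C:0.2):0.05,(D:0.1,E:0.1):0.1,F:0.2);")
        aln = sim.evolve_alignment(tree, 150, poisson, seed=6)
        o1 = phylo.bootstrap_support(aln, poisson, n_reps=10, seed=3)
        o2 = phylo.bootstrap_support(aln, poisson, n_reps=10, seed=3)
        assert o1.as_string(schema="newick") == o2.as_string(schema="newick")
        for nd in o1.postorder_node_iter():
            if nd.label and not nd.is_leaf():
                assert 0.0 <= float(nd.label) <= 100.0


class TestRooting:
    def test_outgroup_rooting_places_outgroup_basally(self):
        t = _tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,OUT:0.5);")
        rooted = phylo.root_with_outgroup(t, ["OUT"])
        kids = rooted.seed_node.child_nodes()
        sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
        assert {"OUT"} in sides

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError):
            phylo.root_with_outgroup(_tree("((A,B),C);"), ["Z"])
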