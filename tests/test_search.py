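"""IC algorithm: decisions, skeleton, colliders, propagation, extension."""

import itertools
from functools import lru_cache

import numpy as np
import networkx as nx
import pytest

import phenonet as pn
from phenonet.search import (
    PartialGraph,
    SearchError,
    _unshielded_colliders_of,
    nested_hpd_intervals,
)

# ---------------------------------------------------------------------------
# oracles

def dsep_decider(dag: nx.DiGraph, labels):
    """Perfect decision function from d-separation in a known DAG."""

    def decide(j, jp, s):
        return nx.is_d_separator(
            dag, {labels[j]}, {labels[jp]}, {labels[k] for k in s}
        )

    return decide


def vstructs(dag: nx.DiGraph):
    out = set()
    for k in dag.nodes:
        for a, b in itertools.combinations(sorted(dag.predecessors(k)), 2):
            if not dag.has_edge(a, b) and not dag.has_edge(b, a):
                out.add((a, k, b))
    return out


@lru_cache(maxsize=None)
def cpdag_class_map(t):
    """Brute force: enumerate every DAG on t labeled nodes, group by
    (skeleton, v-structures), and take the edge-union of each class.  The
    union marks reversible edges as bidirectional: exactly the CPDAG."""
    labels = tuple(chr(ord("A") + i) for i in range(t))
    pairs = list(itertools.combinations(labels, 2))
    classes = {}
    for assignment in itertools.product((0, 1, 2), repeat=len(pairs)):
        dag = nx.DiGraph()
        dag.add_nodes_from(labels)
        for (a, b), kind in zip(pairs, assignment):
            if kind == 1:
                dag.add_edge(a, b)
            elif kind == 2:
                dag.add_edge(b, a)
        if not nx.is_directed_acyclic_graph(dag):
            continue
        skel = frozenset(frozenset(e) for e in dag.to_undirected().edges)
        sig = (skel, frozenset(vstructs(dag)))
        classes.setdefault(sig, set()).update(dag.edges)
    return labels, classes


def cpdag_of(dag: nx.DiGraph, t):
    labels, classes = cpdag_class_map(t)
    skel = frozenset(frozenset(e) for e in dag.to_undirected().edges)
    union = classes[(skel, frozenset(vstructs(dag)))]
    directed = {(a, b) for a, b in union if (b, a) not in union}
    undirected = {tuple(sorted((a, b))) for a, b in union if (b, a) in union}
    return directed, undirected


def random_dag(rng, labels, p=0.45):
    dag = nx.DiGraph()
    dag.add_nodes_from(labels)
    order = list(labels)
    rng.shuffle(order)
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if rng.random() < p:
                dag.add_edge(a, b)
    return dag


def ic_from_oracle(dag, labels):
    decide = dsep_decider(dag, labels)
    skel = pn.ic_skeleton(decide, labels)
    coll = pn.ic_colliders(skel, decide)
    return pn.orient_propagate(coll)


def brute_force_extendable(graph: PartialGraph):
    """Try every orientation of the undirected edges: acyclic and no new
    unshielded collider beyond those of the partially directed input."""
    base_colliders = _unshielded_colliders_of(graph)
    und = sorted(graph.undirected)
    for choice in itertools.product((0, 1), repeat=len(und)):
        g = graph.copy()
        for (a, b), c in zip(und, choice):
            g.undirected.discard(PartialGraph._key(a, b))
            g.directed.add((a, b) if c == 0 else (b, a))
        if g.has_directed_cycle():
            continue
        if _unshielded_colliders_of(g) == base_colliders:
            return True
    return False


# ---------------------------------------------------------------------------
# partial correlations

class TestPartialCorrelation:
    def test_marginal_correlation_of_reported_mtam_residuals(self):
        """With an empty conditioning set the partial correlation is the
        plain correlation; check against the reported MTAM residual
        covariance for the quail traits (BW, AEW entry)."""
        sd = np.sqrt(np.array([0.32, 210.74, 35.19, 0.79, 31.02]))
        corr = np.eye(5)
        entries = {
            (0, 1): 0.03, (0, 2): 0.07, (0, 3): -0.24, (0, 4): -0.07,
            (1, 2): -0.13, (1, 3): 0.12, (1, 4): 0.01,
            (2, 3): -0.08, (2, 4): -0.12, (3, 4): -0.01,
        }
        for (i, j), r in entries.items():
            corr[i, j] = corr[j, i] = r
        sigma = corr * np.outer(sd, sd)
        rho = pn.partial_correlation(sigma, 0, 3, ())
        assert round(rho, 2) == -0.24

    def test_diagonal_sigma_gives_zero(self):
        sigma = np.diag([1.0, 2.0, 3.0, 4.0])
        for j, jp in itertools.combinations(range(4), 2):
            for size in range(3):
                for s in itertools.combinations(
                    [k for k in range(4) if k not in (j, jp)], size
                ):
                    assert pn.partial_correlation(sigma, j, jp, s) == pytest.approx(0)

    def test_matches_regression_residual_oracle(self):
        """rho_{j,j'|k} equals the correlation of residuals from regressing
        j and j' on k (population version, computed from Sigma)."""
        rng = np.random.default_rng(21)
        a = rng.normal(size=(5, 5))
        sigma = a @ a.T + 5 * np.eye(5)
        j, jp, k = 0, 2, 4
        # population regression residual covariance
        res_cov = np.zeros((2, 2))
        for r, x in enumerate((j, jp)):
            for c, y in enumerate((j, jp)):
                res_cov[r, c] = (
                    sigma[x, y] - sigma[x, k] * sigma[k, y] / sigma[k, k]
                )
        expected = res_cov[0, 1] / np.sqrt(res_cov[0, 0] * res_cov[1, 1])
        assert pn.partial_correlation(sigma, j, jp, (k,)) == pytest.approx(expected)

    def test_overlap_rejected(self):
        with pytest.raises(SearchError):
            pn.partial_correlation(np.eye(3), 0, 1, (1,))


class TestHpdInterval:
    def test_constant_samples(self):
        assert pn.hpd_interval([3.3] * 10, 0.9) == (3.3, 3.3)

    def test_1_to_100_window(self):
        lo, hi = pn.hpd_interval(np.arange(1.0, 101.0), 0.95)
        assert (lo, hi) == (1.0, 95.0)  # all windows tie; lowest start wins

    def test_exponential_upper_bound(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(size=100_000)
        lo, hi = pn.hpd_interval(x, 0.9)
        assert lo < 0.01
        assert hi == pytest.approx(-np.log(0.1), abs=0.05)  # 2.3026

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        x = rng.normal(size=50_000)
        lo, hi = pn.hpd_interval(x, 0.95)
        ref = arviz.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_bad_content_rejected(self):
        with pytest.raises(SearchError):
            pn.hpd_interval([1.0, 2.0], 1.0)

    def test_nested_intervals_nest(self):
        rng = np.random.default_rng(17)
        # adversarial: multimodal samples where raw shortest windows
        # need not nest
        x = np.concatenate(
            [rng.normal(0, 0.01, 40), rng.normal(10, 0.2, 60), rng.normal(-4, 2, 30)]
        )
        contents = (0.5, 0.7, 0.9, 0.95)
        iv = nested_hpd_intervals(x, contents)
        for lo_c, hi_c in itertools.pairwise(sorted(contents)):
            assert iv[hi_c][0] <= iv[lo_c][0]
            assert iv[hi_c][1] >= iv[lo_c][1]


class TestIndependenceDecision:
    def test_all_positive_dependent(self):
        assert pn.independence_decision(np.linspace(0.2, 0.6, 50), 0.9) is False

    def test_symmetric_about_zero_null(self):
        x = np.concatenate([np.linspace(-1, 1, 100)])
        for c in (0.5, 0.7, 0.95):
            assert pn.independence_decision(x, c) is True

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            x = rng.uniform(-0.1, 0.9, size=500)
            content = rng.choice([0.5, 0.75, 0.9])
            xs = np.sort(x)
            m = len(xs)
            k = int(np.ceil(content * m))
            widths = xs[k - 1 :] - xs[: m - k + 1]
            i = int(np.argmin(widths))
            expected_null = xs[i] <= 0.0 <= xs[i + k - 1]
            assert pn.independence_decision(x, content) == expected_null


# ---------------------------------------------------------------------------
# IC steps with perfect oracles

class TestSkeleton:
    def test_chain_dag(self):
        dag = nx.DiGraph([("A", "B"), ("B", "C")])
        labels = ("A", "B", "C")
        g = pn.ic_skeleton(dsep_decider(dag, labels), labels)
        assert g.undirected == {("A", "B"), ("B", "C")}
        assert g.sepsets[("A", "C")] == ("B",)

    def test_always_dependent_gives_complete_graph(self):
        labels = ("A", "B", "C", "D")
        g = pn.ic_skeleton(lambda j, jp, s: False, labels)
        assert len(g.undirected) == 6

    def test_random_dags_recover_true_skeleton(self):
        rng = np.random.default_rng(31)
        labels = tuple("ABCDE")
        for _ in range(60):
            dag = random_dag(rng, list(labels))
            g = pn.ic_skeleton(dsep_decider(dag, labels), labels)
            true_skel = {tuple(sorted(e)) for e in dag.to_undirected().edges}
            assert g.undirected == true_skel

    def test_every_absent_edge_has_recorded_sepset(self):
        rng = np.random.default_rng(55)
        labels = tuple("ABCDE")
        dag = random_dag(rng, list(labels))
        decide = dsep_decider(dag, labels)
        g = pn.ic_skeleton(decide, labels)
        for a, b in itertools.combinations(labels, 2):
            if (a, b) not in g.undirected:
                s = g.sepsets[(a, b)]
                ia, ib = labels.index(a), labels.index(b)
                assert decide(ia, ib, tuple(labels.index(x) for x in s))


class TestColliders:
    def test_textbook_v_structure(self):
        dag = nx.DiGraph([("A", "C"), ("B", "C")])
        labels = ("A", "B", "C")
        decide = dsep_decider(dag, labels)
        g = pn.ic_colliders(pn.ic_skeleton(decide, labels), decide)
        assert g.directed == {("A", "C"), ("B", "C")}
        assert g.undirected == set()

    def test_chain_stays_undirected(self):
        dag = nx.DiGraph([("A", "B"), ("B", "C")])
        labels = ("A", "B", "C")
        decide = dsep_decider(dag, labels)
        g = pn.ic_colliders(pn.ic_skeleton(decide, labels), decide)
        assert g.directed == set()
        assert g.undirected == {("A", "B"), ("B", "C")}

    def test_random_dags_recover_true_colliders(self):
        rng = np.random.default_rng(13)
        labels = tuple("ABCDE")
        for _ in range(40):
            dag = random_dag(rng, list(labels))
            decide = dsep_decider(dag, labels)
            g = pn.ic_colliders(pn.ic_skeleton(decide, labels), decide)
            assert _unshielded_colliders_of(g) == vstructs(dag)


class TestPropagation:
    def test_meek_r1(self):
        g = PartialGraph(nodes=("A", "B", "C"))
        g.directed.add(("A", "B"))
        g.add_undirected("B", "C")
        out = pn.orient_propagate(g)
        assert ("B", "C") in out.directed

    def test_undirected_triangle_unchanged(self):
        g = PartialGraph(nodes=("A", "B", "C"))
        for a, b in itertools.combinations("ABC", 2):
            g.add_undirected(a, b)
        out = pn.orient_propagate(g)
        assert out.directed == set()
        assert len(out.undirected) == 3

    def test_meek_r4_forced_orientation(self):
        """Configuration where only R4 fires: verified against brute-force
        enumeration of consistent extensions."""
        g = PartialGraph(nodes=("A", "B", "C", "D"))
        g.add_undirected("A", "B")
        g.add_undirected("A", "D")
        g.add_undirected("A", "C")
        g.directed.add(("D", "C"))
        g.directed.add(("C", "B"))
        out = pn.orient_propagate(g)
        assert ("A", "B") in out.directed
        # cross-check: every consistent extension orients A -> B
        base = PartialGraph(nodes=("A", "B", "C", "D"))
        base.add_undirected("A", "D")
        base.add_undirected("A", "C")
        base.directed |= {("D", "C"), ("C", "B"), ("A", "B")}
        assert brute_force_extendable(base)
        rev = base.copy()
        rev.directed = {("D", "C"), ("C", "B"), ("B", "A")}
        assert not brute_force_extendable(rev)

    def test_equals_cpdag_on_random_dags(self):
        rng = np.random.default_rng(101)
        labels = tuple("ABCDE")
        for _ in range(60):
            dag = random_dag(rng, list(labels))
            out = ic_from_oracle(dag, labels)
            directed, undirected = cpdag_of(dag, 5)
            assert out.directed == directed
            assert out.undirected == undirected


class TestConsistentExtension:
    def test_chordless_four_cycle_not_extendable(self):
        g = PartialGraph(nodes=("A", "B", "C", "D"))
        for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]:
            g.add_undirected(a, b)
        ok, witness = pn.has_consistent_extension(g)
        assert ok is False and witness is None

    def test_tree_extendable(self):
        g = PartialGraph(nodes=("A", "B", "C", "D"))
        for a, b in [("A", "B"), ("B", "C"), ("B", "D")]:
            g.add_undirected(a, b)
        ok, witness = pn.has_consistent_extension(g)
        assert ok is True
        dag = nx.DiGraph(sorted(witness))
        dag.add_nodes_from(g.nodes)
        assert nx.is_directed_acyclic_graph(dag)
        assert vstructs(dag) == set()

    def test_agrees_with_brute_force_on_random_mixed_graphs(self):
        rng = np.random.default_rng(2024)
        labels = tuple("ABCDEF")
        for _ in range(150):
            n = int(rng.integers(3, 7))
            nodes = labels[:n]
            g = PartialGraph(nodes=nodes)
            for a, b in itertools.combinations(nodes, 2):
                r = rng.random()
                if r < 0.25:
                    g.add_undirected(a, b)
                elif r < 0.40:
                    g.directed.add((a, b) if rng.random() < 0.5 else (b, a))
            ok, witness = pn.has_consistent_extension(g)
            assert ok == brute_force_extendable(g)
            if ok:
                dag = nx.DiGraph(sorted(witness))
                dag.add_nodes_from(nodes)
                assert nx.is_directed_acyclic_graph(dag)
                assert set(g.directed) <= set(witness)
                assert _unshielded_colliders_of(g) == vstructs(dag)


class TestTemporalOrient:
    def test_quail_edges_follow_time(self):
        g = PartialGraph(nodes=pn.TRAITS)
        for a, b in [("AEW", "BW"), ("AFE", "W35"), ("AFE", "NE")]:
            g.add_undirected(a, b)
        out = pn.temporal_orient(g, pn.DEFAULT_TIME_ORDER)
        assert out.directed == {("BW", "AEW"), ("W35", "AFE"), ("AFE", "NE")}
        assert out.undirected == set()

    def test_single_time_point_unchanged(self):
        g = PartialGraph(nodes=("A", "B"))
        g.add_undirected("A", "B")
        out = pn.temporal_orient(g, {"A": 0, "B": 0})
        assert out.undirected == {("A", "B")}
        assert any("tied" in n for n in out.notes)

    def test_created_collider_is_reported(self):
        g = PartialGraph(nodes=pn.TRAITS)
        for a, b in [("AEW", "BW"), ("AEW", "W35"), ("AFE", "W35"), ("AFE", "NE")]:
            g.add_undirected(a, b)
        out = pn.temporal_orient(g, pn.DEFAULT_TIME_ORDER)
        assert ("W35", "AEW") in out.directed
        assert any("BW -> AEW <- W35" in n for n in out.notes)

    def test_conflicting_directed_edge_errors(self):
        g = PartialGraph(nodes=("BW", "AEW"))
        g.directed.add(("AEW", "BW"))
        with pytest.raises(SearchError, match="AEW -> BW"):
            pn.temporal_orient(g, pn.DEFAULT_TIME_ORDER)


class TestPosteriorDecisions:
    def test_sharp_samples_reproduce_point_estimate_search(self):
        """Nearly-degenerate posterior draws around a known covariance give
        the same graph as exact d-separation decisions."""
        dag = nx.DiGraph([("A", "B"), ("B", "C")])
        labels = ("A", "B", "C")
        lam = np.zeros((3, 3))
        lam[1, 0] = 0.8
        lam[2, 1] = 0.8
        sigma = pn.reduce_residual_covariance(lam, np.ones(3))
        draws = np.stack([sigma] * 200)
        res = pn.search_over_contents(draws, labels, (0.95,))
        oracle = ic_from_oracle(dag, labels)
        assert res.graphs[0.95].undirected == oracle.undirected
        assert res.graphs[0.95].directed == oracle.directed

    def test_higher_content_prunes_edges(self):
        """With nested intervals, every edge present at 95% is present at
        70% for the same draws."""
        rng = np.random.default_rng(42)
        base = np.array(
            [[1.0, 0.12, 0.0], [0.12, 1.0, 0.3], [0.0, 0.3, 1.0]]
        )
        x = rng.multivariate_normal(np.zeros(3), base, size=400)
        draws = np.stack(
            [np.cov(x[rng.integers(400, size=200)].T) for _ in range(300)]
        )
        res = pn.search_over_contents(draws, ("A", "B", "C"), (0.70, 0.95))
        assert res.graphs[0.95].skeleton_edges() <= res.graphs[0.70].skeleton_edges()
        assert res.stable_edges == res.graphs[0.95].skeleton_edges()

    def test_null_truth_rarely_finds_edges(self):
        """Diagonal-covariance truth: the searched graph is empty in most
        replicates at high content (false edges need every conditioning
        subset to look dependent)."""
        rng = np.random.default_rng(3)
        n, m = 200, 300
        empty = 0
        reps = 20
        for _ in range(reps):
            x = rng.standard_normal((n, 4))
            draws = np.stack(
                [np.cov(x[rng.integers(n, size=n)].T) for _ in range(m)]
            )
            res = pn.search_over_contents(draws, ("A", "B", "C", "D"), (0.95,))
            empty += not res.graphs[0.95].skeleton_edges()
        assert empty >= 0.8 * reps

    def test_excessive_singular_draws_error(self):
        draws = np.zeros((100, 3, 3))  # singular everywhere
        pdf = pn.PosteriorDecisionFunction(draws, ("A", "B", "C"), (0.9,))
        with pytest.raises(SearchError, match="singular"):
            pdf.decide(0, 1, (), 0.9)

    def test_decision_log_is_complete(self, small_fr_chain):
        res = pn.search_over_contents(
            small_fr_chain.r0_star, pn.TRAITS, (0.90,)
        )
        g = res.graphs[0.90]
        logged = {(r.pair, r.conditioning) for r in g.decision_log}
        assert logged  # every query left a record
        for a, b in itertools.combinations(pn.TRAITS, 2):
            key = PartialGraph._key(a, b)
            if key not in g.skeleton_edges():
                assert key in g.sepsets
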