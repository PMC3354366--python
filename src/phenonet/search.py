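"""Inductive Causation (IC) over posterior samples of a residual covariance.

The search operates on the phenotypic covariance conditional on additive
genetic effects (the MTAM residual covariance R0*), because genetic
covariances would otherwise confound the phenotype-level independencies.
Every conditional-independence query about traits j, j' given a set S is
answered statistically: the residual partial correlation rho_{j,j'|S} is
computed at each posterior draw of R0*, the highest-posterior-density (HPD)
interval of the resulting sample is formed at a chosen probability content,
and the correlation is declared null iff the interval contains zero.

Steps: (1) skeleton — an edge is absent iff some conditioning subset yields
a null verdict (exhaustive over all subsets; trivial at t = 5); (2)
unshielded-collider discovery; (3) Meek-rule orientation propagation.
Temporal background knowledge can then orient remaining undirected edges,
overriding the algorithm where prior knowledge is firmer than data
evidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# partial correlations and HPD intervals

def partial_correlation(sigma: np.ndarray, j: int, jp: int, s: tuple[int, ...]) -> float:
    """Partial correlation of variables j, j' given the set S.

    Computed on the precision scale of the ({j, j'} | S)-submatrix:
    rho = -omega_{j j'} / sqrt(omega_{jj} omega_{j'j'}).  Raises
    ``numpy.linalg.LinAlgError`` for a singular submatrix; callers decide
    whether to skip the draw.
    """
    if j == jp or j in s or jp in s:
        raise SearchError("query indices must be distinct from the conditioning set")
    idx = [j, jp, *s]
    sub = np.asarray(sigma, dtype=float)[np.ix_(idx, idx)]
    omega = np.linalg.inv(sub)
    denom = omega[0, 0] * omega[1, 1]
    if denom <= 0:
        raise np.linalg.LinAlgError("non-positive precision diagonal")
    return float(-omega[0, 1] / math.sqrt(denom))


def hpd_interval(samples, content: float) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(content * m)`` of the m
    sorted samples; ties broken by the lowest start index."""
    if not 0.0 < content < 1.0:
        raise SearchError(f"HPD content must lie in (0, 1), got {content}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise SearchError("need at least 2 finite samples")
    m = x.size
    k = math.ceil(content * m)
    widths = x[k - 1 :] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def nested_hpd_intervals(
    samples, contents: tuple[float, ...]
) -> dict[float, tuple[float, float]]:
    """HPD intervals for several contents, nested by construction.

    The lowest content gets the plain shortest window; each higher content
    gets the shortest window that contains the previous one.  Nesting makes
    the null verdict monotone in the content (a wider interval containing a
    narrower one that covers zero still covers zero), which the raw
    shortest-window estimator does not guarantee for multimodal samples.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise SearchError("need at least 2 finite samples")
    m = x.size
    out: dict[float, tuple[float, float]] = {}
    prev_i = prev_j = None
    for c in sorted(contents):
        if not 0.0 < c < 1.0:
            raise SearchError(f"HPD content must lie in (0, 1), got {c}")
        k = math.ceil(c * m)
        if prev_i is None:
            widths = x[k - 1 :] - x[: m - k + 1]
            i = int(np.argmin(widths))
        else:
            lo = max(0, prev_j - k + 1)
            hi = min(prev_i, m - k)
            cand = np.arange(lo, hi + 1)
            widths = x[cand + k - 1] - x[cand]
            i = int(cand[np.argmin(widths)])
        out[c] = (float(x[i]), float(x[i + k - 1]))
        prev_i, prev_j = i, i + k - 1
    return out


#: absolute floating-point guard for the "interval contains zero" rule, so
#: that an exactly-zero partial correlation computed with rounding error
#: still counts as containing zero
_ZERO_TOL = 1e-12


def _contains_zero(lo: float, hi: float) -> bool:
    return lo <= _ZERO_TOL and hi >= -_ZERO_TOL


def independence_decision(samples, content: float) -> bool:
    """True (null) iff the HPD interval at ``content`` contains zero;
    boundary values count as containing zero."""
    lo, hi = hpd_interval(samples, content)
    return _contains_zero(lo, hi)


# ---------------------------------------------------------------------------
# decision layer over posterior draws

@dataclass(frozen=True)
class DecisionRecord:
    """One conditional-independence query and its verdict."""

    pair: tuple[str, str]
    conditioning: tuple[str, ...]
    mean: float
    hpd_lower: float
    hpd_upper: float
    content: float
    null: bool
    n_skipped: int = 0


class PosteriorDecisionFunction:
    """Answers independence queries from posterior draws of R0*.

    Per-query partial-correlation samples are cached, so re-queries at
    other contents (Step 2 of IC, multi-content searches) reuse them; the
    intervals for a content list are nested by construction.  Draws with a
    singular submatrix are skipped and counted; a query errors if more than
    ``max_skip_fraction`` of draws were dropped.
    """

    def __init__(
        self,
        r0_samples: np.ndarray,
        traits: tuple[str, ...],
        contents: tuple[float, ...] = (0.95,),
        max_skip_fraction: float = 0.01,
    ):
        self.r0 = np.asarray(r0_samples, dtype=float)
        if self.r0.ndim != 3 or self.r0.shape[1] != self.r0.shape[2]:
            raise SearchError("r0_samples must be (m, t, t)")
        self.traits = tuple(traits)
        self.contents = tuple(sorted(contents))
        self.max_skip_fraction = max_skip_fraction
        self._rho_cache: dict[tuple, tuple[np.ndarray, int]] = {}
        self._interval_cache: dict[tuple, dict[float, tuple[float, float]]] = {}
        self.log: list[DecisionRecord] = []

    def rho_samples(self, j: int, jp: int, s: tuple[int, ...]) -> tuple[np.ndarray, int]:
        key = (j, jp, tuple(sorted(s)))
        if key not in self._rho_cache:
            vals = []
            skipped = 0
            for sigma in self.r0:
                try:
                    vals.append(partial_correlation(sigma, j, jp, key[2]))
                except np.linalg.LinAlgError:
                    skipped += 1
            if skipped > self.max_skip_fraction * len(self.r0):
                raise SearchError(
                    f"query ({self.traits[j]}, {self.traits[jp]} | "
                    f"{[self.traits[i] for i in key[2]]}): {skipped} of "
                    f"{len(self.r0)} draws singular"
                )
            self._rho_cache[key] = (np.asarray(vals), skipped)
        return self._rho_cache[key]

    def decide(
        self, j: int, jp: int, s: tuple[int, ...], content: float
    ) -> DecisionRecord:
        key = (j, jp, tuple(sorted(s)))
        rho, skipped = self.rho_samples(j, jp, s)
        if key not in self._interval_cache:
            contents = self.contents if content in self.contents else tuple(
                sorted({*self.contents, content})
            )
            self._interval_cache[key] = nested_hpd_intervals(rho, contents)
        intervals = self._interval_cache[key]
        if content not in intervals:
            self._interval_cache[key] = nested_hpd_intervals(
                rho, tuple(sorted({*intervals, content}))
            )
            intervals = self._interval_cache[key]
        lo, hi = intervals[content]
        rec = DecisionRecord(
            pair=(self.traits[j], self.traits[jp]),
            conditioning=tuple(self.traits[i] for i in key[2]),
            mean=float(np.mean(rho)),
            hpd_lower=lo,
            hpd_upper=hi,
            content=content,
            null=_contains_zero(lo, hi),
            n_skipped=skipped,
        )
        self.log.append(rec)
        return rec

    def decision_function(self, content: float):
        """Plain (j, j', S) -> null? callable at a fixed content."""

        def decide(j: int, jp: int, s: tuple[int, ...]) -> bool:
            return self.decide(j, jp, s, content).null

        return decide


# ---------------------------------------------------------------------------
# the mixed graph

@dataclass
class PartialGraph:
    """Mixed graph over traits: undirected + directed edges.

    ``sepsets`` records, per non-adjacent pair, the first separating set
    found; ``decision_log`` the full evidence trail; ``conflicts`` any
    edges demanded in both directions by different collider triples (kept
    out of both edge sets, reported, never silently resolved).
    """

    nodes: tuple[str, ...]
    undirected: set[tuple[str, str]] = field(default_factory=set)
    directed: set[tuple[str, str]] = field(default_factory=set)
    sepsets: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    decision_log: list = field(default_factory=list)
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_undirected(self, a: str, b: str) -> None:
        self.undirected.add(self._key(a, b))

    def adjacent(self, a: str, b: str) -> bool:
        return (
            self._key(a, b) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def neighbors(self, a: str) -> set[str]:
        out = set()
        for x, y in self.undirected:
            if a == x:
                out.add(y)
            elif a == y:
                out.add(x)
        for x, y in self.directed:
            if a == x:
                out.add(y)
            elif a == y:
                out.add(x)
        return out

    def undirected_neighbors(self, a: str) -> set[str]:
        return {y if x == a else x for x, y in self.undirected if a in (x, y)}

    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a-b into a -> b."""
        self.undirected.discard(self._key(a, b))
        self.directed.add((a, b))

    def all_edges(self) -> set[tuple[str, str]]:
        return set(self.undirected) | set(self.directed)

    def skeleton_edges(self) -> set[tuple[str, str]]:
        return {self._key(a, b) for a, b in self.all_edges()}

    def copy(self) -> "PartialGraph":
        return PartialGraph(
            nodes=self.nodes,
            undirected=set(self.undirected),
            directed=set(self.directed),
            sepsets=dict(self.sepsets),
            decision_log=list(self.decision_log),
            conflicts=list(self.conflicts),
            notes=list(self.notes),
        )

    def has_directed_cycle(self) -> bool:
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.directed:
            indeg[b] += 1
        queue = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for a, b in self.directed:
                if a == n:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        return seen < len(self.nodes)

    # -- serialization ------------------------------------------------------

    def to_edge_list(self) -> str:
        lines = [f"# traits: {','.join(self.nodes)}"]
        lines += [f"{a} -> {b}" for a, b in sorted(self.directed)]
        lines += [f"{a} -- {b}" for a, b in sorted(self.undirected)]
        for a, b in self.conflicts:
            lines.append(f"{a} <-> {b}  # conflict")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph partial_graph {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in sorted(self.directed):
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in sorted(self.undirected):
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
        for a, b in self.conflicts:
            lines.append(f'  "{a}" -> "{b}" [dir=both, color=red];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in self.directed:
            g.add_edge(a, b, kind="directed")
        for a, b in self.undirected:
            g.add_edge(a, b, kind="undirected")
        return g


# ---------------------------------------------------------------------------
# IC steps

def _normalize_decider(decide):
    """Accept either a bool-returning callable or one returning objects
    with a ``null`` attribute."""

    def wrapped(j, jp, s):
        res = decide(j, jp, tuple(s))
        return res.null if hasattr(res, "null") else bool(res)

    return wrapped


def ic_skeleton(decide, traits) -> PartialGraph:
    """IC Step 1: the undirected skeleton plus separating sets.

    An edge j-j' is absent iff SOME conditioning subset yields a null
    verdict; subsets are enumerated exhaustively in increasing size,
    lexicographically (by trait order) within size, and the first
    separating set is recorded.
    """
    traits = tuple(traits)
    null_of = _normalize_decider(decide)
    g = PartialGraph(nodes=traits)
    t = len(traits)
    for j, jp in itertools.combinations(range(t), 2):
        rest = [k for k in range(t) if k not in (j, jp)]
        separated = False
        for size in range(len(rest) + 1):
            for s in itertools.combinations(rest, size):
                if null_of(j, jp, s):
                    g.sepsets[PartialGraph._key(traits[j], traits[jp])] = tuple(
                        traits[k] for k in s
                    )
                    separated = True
                    break
            if separated:
                break
        if not separated:
            g.add_undirected(traits[j], traits[jp])
    return g


def ic_colliders(skeleton: PartialGraph, decide) -> PartialGraph:
    """IC Step 2: orient unshielded triples j - k - j' as colliders.

    For each such triple with j, j' non-adjacent, every conditioning set
    containing k is re-queried; the collider j -> k <- j' is added iff no
    such set yields a null verdict.  Contradictory demands on an edge are
    recorded as conflicts and the edge is withdrawn from both edge sets.
    """
    traits = skeleton.nodes
    t = len(traits)
    null_of = _normalize_decider(decide)
    g = skeleton.copy()
    want: set[tuple[str, str]] = set()
    for j, jp in itertools.combinations(range(t), 2):
        a, b = traits[j], traits[jp]
        if g.adjacent(a, b):
            continue
        common = g.neighbors(a) & g.neighbors(b)
        for k_lab in sorted(common, key=traits.index):
            k = traits.index(k_lab)
            rest = [x for x in range(t) if x not in (j, jp, k)]
            any_null = False
            for size in range(len(rest) + 1):
                for extra in itertools.combinations(rest, size):
                    if null_of(j, jp, (k, *extra)):
                        any_null = True
                        break
                if any_null:
                    break
            if not any_null:
                want.add((a, k_lab))
                want.add((b, k_lab))
    conflicted = {
        PartialGraph._key(a, b) for a, b in want if (b, a) in want
    }
    for a, b in sorted(want):
        key = PartialGraph._key(a, b)
        if key in conflicted:
            continue
        g.orient(a, b)
    for key in sorted(conflicted):
        g.undirected.discard(key)
        g.conflicts.append(key)
        g.notes.append(f"collider conflict on edge {key[0]}-{key[1]}")
    return g


def orient_propagate(graph: PartialGraph) -> PartialGraph:
    """IC Step 3: Meek rules R1-R4 applied to a fixed point.

    Orientations are forced whenever the alternative would create a new
    unshielded collider or a directed cycle.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for a, b in sorted(g.undirected):
            for x, y in ((a, b), (b, a)):
                if _meek_applies(g, x, y):
                    g.orient(x, y)
                    changed = True
                    break
            if changed:
                break
    return g


def _meek_applies(g: PartialGraph, x: str, y: str) -> bool:
    """Would some Meek rule orient the undirected edge x-y as x -> y?"""
    # R1: z -> x, x - y, z and y non-adjacent  =>  x -> y
    for z, w in g.directed:
        if w == x and z != y and not g.adjacent(z, y):
            return True
    # R2: x -> z -> y and x - y  =>  x -> y
    for z in g.nodes:
        if (x, z) in g.directed and (z, y) in g.directed:
            return True
    # R3: x - z, x - w, z -> y, w -> y, z and w non-adjacent  =>  x -> y
    und = g.undirected_neighbors(x)
    into_y = [z for z in und if (z, y) in g.directed]
    for z, w in itertools.combinations(sorted(into_y), 2):
        if not g.adjacent(z, w):
            return True
    # R4: x - w, w -> z, z -> y, w and y non-adjacent, x adjacent to z
    for w in und:
        for z in g.nodes:
            if (
                (w, z) in g.directed
                and (z, y) in g.directed
                and not g.adjacent(w, y)
                and g.adjacent(x, z)
            ):
                return True
    return False


def has_consistent_extension(graph: PartialGraph):
    """Is there an acyclic full orientation creating no new unshielded
    collider?  (Dor-Tarsi sink elimination.)  Returns (bool, witness DAG
    edge set or None); existing directed edges are preserved.
    """
    if graph.has_directed_cycle():
        return False, None
    work = graph.copy()
    witness = set(graph.directed)
    remaining = set(graph.nodes)
    while remaining:
        found = None
        for x in sorted(remaining):
            # sink condition: no directed edge out of x among remaining
            if any(a == x and b in remaining for a, b in work.directed):
                continue
            und = {u for u in work.undirected_neighbors(x) if u in remaining}
            others = {u for u in work.neighbors(x) if u in remaining} - {x}
            ok = all(
                work.adjacent(u, v) for u in und for v in others if u != v
            )
            if ok:
                found = x
                break
        if found is None:
            return False, None
        for u in {n for n in work.undirected_neighbors(found) if n in remaining}:
            witness.add((u, found))
            work.undirected.discard(PartialGraph._key(u, found))
        remaining.discard(found)
        work.directed = {
            (a, b) for a, b in work.directed if a in remaining and b in remaining
        }
    return True, witness


def temporal_orient(graph: PartialGraph, time_order: dict[str, int]) -> PartialGraph:
    """Orient undirected edges between temporally comparable traits
    earlier -> later, overriding the algorithm output.

    Newly created unshielded colliders are reported in ``notes``; edges
    between traits tied in time stay undirected and are listed; a directed
    edge already pointing against time is an error.
    """
    g = graph.copy()
    for a, b in g.directed:
        ra, rb = time_order.get(a), time_order.get(b)
        if ra is not None and rb is not None and ra > rb:
            raise SearchError(
                f"edge {a} -> {b} conflicts with the temporal order"
            )
    pre_colliders = _unshielded_colliders_of(g)
    for a, b in sorted(g.undirected):
        ra, rb = time_order.get(a), time_order.get(b)
        if ra is None or rb is None or ra == rb:
            g.notes.append(f"edge {a}-{b} left undirected (temporally tied)")
            continue
        if ra < rb:
            g.orient(a, b)
        else:
            g.orient(b, a)
    for coll in _unshielded_colliders_of(g) - pre_colliders:
        j, k, jp = coll
        g.notes.append(
            f"temporal orienting created unshielded collider {j} -> {k} <- {jp}"
        )
    return g


def _unshielded_colliders_of(g: PartialGraph) -> set[tuple[str, str, str]]:
    out = set()
    for (a, k1), (b, k2) in itertools.combinations(sorted(g.directed), 2):
        if k1 == k2 and a != b and not g.adjacent(a, b):
            j, jp = sorted((a, b))
            out.add((j, k1, jp))
    return out


# ---------------------------------------------------------------------------
# multi-content search

@dataclass
class SearchResult:
    graphs: dict[float, PartialGraph]
    stable_edges: set[tuple[str, str]]
    decision_function: PosteriorDecisionFunction

    def stability_report(self) -> str:
        lines = []
        for c, g in sorted(self.graphs.items()):
            edges = ", ".join(f"{a}-{b}" for a, b in sorted(g.skeleton_edges()))
            lines.append(f"HPD {c:.0%}: {edges or '(empty)'}")
        stable = ", ".join(f"{a}-{b}" for a, b in sorted(self.stable_edges))
        lines.append(f"most stable (present at every content): {stable or '(none)'}")
        return "\n".join(lines)


def search_over_contents(
    r0_samples: np.ndarray,
    traits: tuple[str, ...],
    contents: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
) -> SearchResult:
    """Full IC run (skeleton, colliders, propagation) per HPD content.

    Partial-correlation samples are shared across contents; intervals are
    nested, so a higher content can only prune edges relative to a lower
    one for the same query.  Edges present at every content are flagged as
    the most stable.
    """
    if not contents:
        raise SearchError("need at least one HPD content")
    pdf = PosteriorDecisionFunction(r0_samples, traits, tuple(contents))
    graphs: dict[float, PartialGraph] = {}
    for c in sorted(contents):
        decide = pdf.decision_function(c)
        skel = ic_skeleton(decide, traits)
        coll = ic_colliders(skel, decide)
        final = orient_propagate(coll)
        final.decision_log = [r for r in pdf.log if r.content == c]
        graphs[c] = final
    edge_sets = [g.skeleton_edges() for g in graphs.values()]
    stable = set.intersection(*edge_sets) if edge_sets else set()
    return SearchResult(graphs=graphs, stable_edges=stable, decision_function=pdf)
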