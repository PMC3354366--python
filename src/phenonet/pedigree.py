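"""Pedigree validation and additive-relationship-matrix algebra.

The additive (numerator) relationship matrix ``A`` holds expected additive
genetic relationships between all pedigree members and structures the
covariance ``G0 (x) A`` of the additive genetic effects in the multivariate
animal model.  Both the dense tabular construction (with inbreeding
accumulated) and the sparse direct inverse (Henderson's rules extended for
inbreeding) are provided: the forward matrix is what simulation needs, the
inverse is what Gibbs sampling of the genetic effects needs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: sentinel for an unknown parent (internal representation)
UNKNOWN: str | None = None

_UNKNOWN_TOKENS = {"", "0", "na", "nan", ".", "none", "unknown"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree: parents always precede offspring.

    ``records`` is a tuple of ``(animal, sire, dam)`` with ``None`` marking
    an unknown parent.  IDs are opaque strings; no numeric ordering is ever
    assumed.
    """

    records: tuple[tuple[str, str | None, str | None], ...]
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self._index:
            object.__setattr__(
                self, "_index", {a: i for i, (a, _, _) in enumerate(self.records)}
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def index_of(self, animal: str) -> int:
        return self._index[animal]

    def parent_indices(self) -> np.ndarray:
        """(q, 2) array of parent row indices, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s is not None:
                out[i, 0] = self._index[s]
            if d is not None:
                out[i, 1] = self._index[d]
        return out


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix with its id -> row index map."""

    entries: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.ids)})

    def loc(self, a: str, b: str) -> float:
        return float(self.entries[self._index[a], self._index[b]])

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.entries) - 1.0


def _normalize_parent(token) -> str | None:
    if token is None:
        return None
    t = str(token).strip()
    if t.lower() in _UNKNOWN_TOKENS:
        return None
    return t


def validate_and_sort(records) -> Pedigree:
    """Validate raw ``(animal, sire, dam)`` triples and topologically sort.

    The output order is deterministic: stable sort by generation depth
    (founders first), ties broken by input order.  Unknown parents may be
    coded as ``None``, ``""`` or ``"0"``.

    Raises
    ------
    PedigreeError
        On duplicate IDs, parents never defined as animals, or parentage
        cycles (including self-ancestry); the offending ID is named.
    """
    triples: list[tuple[str, str | None, str | None]] = []
    seen: set[str] = set()
    for rec in records:
        a, s, d = rec[0], _normalize_parent(rec[1]), _normalize_parent(rec[2])
        a = str(a).strip()
        if not a or a.lower() in _UNKNOWN_TOKENS:
            raise PedigreeError(f"invalid animal id {rec[0]!r}")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        triples.append((a, s, d))

    parents_of = {a: (s, d) for a, s, d in triples}
    for a, s, d in triples:
        for p in (s, d):
            if p is not None and p not in parents_of:
                raise PedigreeError(
                    f"parent {p!r} of animal {a!r} never defined as an animal"
                )

    # iterative depth computation with cycle detection (no recursion limit)
    depth: dict[str, int] = {}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {a: WHITE for a in parents_of}
    for root, _, _ in triples:
        if color[root] == BLACK:
            continue
        stack = [root]
        while stack:
            node = stack[-1]
            if color[node] == WHITE:
                color[node] = GREY
                for p in parents_of[node]:
                    if p is None:
                        continue
                    if color[p] == GREY:
                        raise PedigreeError(
                            f"parentage cycle involving animal {p!r}"
                        )
                    if color[p] == WHITE:
                        stack.append(p)
            else:
                stack.pop()
                if color[node] == BLACK:
                    continue
                color[node] = BLACK
                s, d = parents_of[node]
                depth[node] = 1 + max(
                    depth[s] if s is not None else -1,
                    depth[d] if d is not None else -1,
                )

    order = sorted(range(len(triples)), key=lambda i: (depth[triples[i][0]], i))
    return Pedigree(records=tuple(triples[i] for i in order))


def relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Inbreeding accumulates through the recursion, so the diagonal is
    ``1 + F_i``.  Dense O(q^2); fine up to a few thousand animals, which is
    the scale the simulator targets.
    """
    q = len(pedigree)
    par = pedigree.parent_indices()
    A = np.zeros((q, q))
    for i in range(q):
        s, d = par[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        row = np.zeros(q)
        if s >= 0:
            row[:i] += 0.5 * A[s, :i]
        if d >= 0:
            row[:i] += 0.5 * A[d, :i]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
    return RelationshipMatrix(entries=A, ids=tuple(pedigree.ids))


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i via memoized kinship recursion.

    Avoids the O(q^2) tabular matrix: only kinships actually reachable from
    mated pairs are evaluated.
    """
    par = pedigree.parent_indices()
    q = len(pedigree)
    memo: dict[tuple[int, int], float] = {}

    def kinship(i: int, j: int) -> float:
        # iterative-on-demand with explicit stack to respect deep pedigrees
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        stack = [key]
        while stack:
            a, b = stack[-1]
            if (a, b) in memo:
                stack.pop()
                continue
            if a == b:
                s, d = par[a]
                if s >= 0 and d >= 0:
                    k = (s, d) if s <= d else (d, s)
                    if k not in memo:
                        stack.append(k)
                        continue
                    memo[(a, b)] = 0.5 * (1.0 + memo[k])
                else:
                    memo[(a, b)] = 0.5
                stack.pop()
                continue
            # reduce the younger member (larger topological index)
            y, o = (b, a) if b > a else (a, b)
            s, d = par[y]
            need = []
            for p in (s, d):
                if p >= 0:
                    k = (p, o) if p <= o else (o, p)
                    if k not in memo:
                        need.append(k)
            if need:
                stack.extend(need)
                continue
            val = 0.0
            for p in (s, d):
                if p >= 0:
                    k = (p, o) if p <= o else (o, p)
                    val += 0.5 * memo[k]
            memo[(a, b)] = val
            stack.pop()
        return memo[key]

    F = np.zeros(q)
    for i in range(q):
        s, d = par[i]
        if s >= 0 and d >= 0:
            F[i] = kinship(s, d)
    return F


def a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of the relationship matrix, inbreeding accounted for.

    Assembled from per-individual Mendelian-sampling variances
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (both parents known),
    ``0.75 - 0.25 F_p`` (one known) or ``1`` (founders), via the standard
    rules: ``1/d_i`` at (i,i), ``-1/(2 d_i)`` between i and each known
    parent, and ``1/(4 d_i)`` among known parents.
    """
    q = len(pedigree)
    par = pedigree.parent_indices()
    F = inbreeding_coefficients(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(q):
        s, d = par[i]
        known = [p for p in (s, d) if p >= 0]
        if len(known) == 2:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif len(known) == 1:
            di = 0.75 - 0.25 * F[known[0]]
        else:
            di = 1.0
        m = 1.0 / di
        add(i, i, m)
        for p in known:
            add(i, p, -0.5 * m)
            add(p, i, -0.5 * m)
        for p in known:
            for r in known:
                add(p, r, 0.25 * m)
    return sp.csr_matrix((vals, (rows, cols)), shape=(q, q))


# ---------------------------------------------------------------------------
# file I/O

def read_pedigree(path_or_buffer) -> Pedigree:
    """Read a 3-column delimited pedigree file (animal, sire, dam).

    Header row optional; comma or tab sniffed; ``0`` or an empty field means
    an unknown parent.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", newline="") as fh:
            text = fh.read()
    sample = text[:2048]
    delim = "\t" if sample.count("\t") >= sample.count(",") else ","
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    raw = [row for row in reader if row and any(c.strip() for c in row)]
    if not raw:
        raise PedigreeError("empty pedigree file")
    # header detection: first row repeated nowhere as a parent and looks wordy
    first = [c.strip().lower() for c in raw[0]]
    if any(w in ("animal", "id", "sire", "dam", "father", "mother") for w in first):
        raw = raw[1:]
    triples = []
    for row in raw:
        if len(row) < 3:
            raise PedigreeError(f"pedigree row with fewer than 3 columns: {row!r}")
        triples.append((row[0], row[1], row[2]))
    return validate_and_sort(triples)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal", "sire", "dam"])
        for a, s, d in pedigree.records:
            w.writerow([a, s or "0", d or "0"])
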