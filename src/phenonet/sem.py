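"""Recursive structural equation model (SEM) parameterization and algebra.

A recursive SEM over ``t`` traits lets each trait's phenotype depend
linearly on other traits' phenotypes through a structural-coefficient
matrix ``Lambda`` (zero diagonal; nonzero pattern given by an acyclic
causal structure), plus fixed effects, additive genetic effects and
independent residuals:

    y_i = Lambda y_i + beta[season_i] + u_i + e_i,      e_i ~ N(0, Psi0)

with ``Psi0`` diagonal (causal sufficiency: no residual covariance between
traits).  Solving for ``y_i`` gives the reduced model

    y_i = (I - Lambda)^-1 (beta[season_i] + u_i + e_i)

which maps SEM dispersion parameters onto the multiple-trait-animal-model
(MTAM) scale:  R0* = (I-Lambda)^-1 Psi0 (I-Lambda)^-T is the residual
covariance of the phenotypes conditional on the genetic effects, and the
genetic covariance transforms the same way.  Because any positive-definite
MTAM residual covariance factorizes this way under a fixed trait order
(LDL), a fully recursive SEM is likelihood-equivalent to the MTAM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular


class StructureError(ValueError):
    """Raised for cyclic or otherwise invalid causal structures."""


@dataclass(frozen=True)
class CausalStructure:
    """Trait DAG: which phenotypes directly affect which.

    ``edges`` are (parent, child) trait-label pairs; the structure defines
    exactly the free off-diagonal entries of ``Lambda`` (child row, parent
    column).
    """

    traits: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        idx = {t: i for i, t in enumerate(self.traits)}
        if len(idx) != len(self.traits):
            raise StructureError("duplicate trait labels")
        for p, c in self.edges:
            if p not in idx or c not in idx:
                raise StructureError(f"edge ({p!r}, {c!r}) uses unknown trait")
            if p == c:
                raise StructureError(f"self-edge on trait {p!r}")
        if self._topological_order() is None:
            raise StructureError("causal structure contains a cycle")

    @property
    def t(self) -> int:
        return len(self.traits)

    def index(self, trait: str) -> int:
        return self.traits.index(trait)

    def parents(self, trait: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == trait))

    def _topological_order(self) -> list[str] | None:
        indeg = {t: 0 for t in self.traits}
        for _, c in self.edges:
            indeg[c] += 1
        queue = [t for t in self.traits if indeg[t] == 0]
        order = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for p, c in sorted(self.edges):
                if p == n:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        queue.append(c)
        return order if len(order) == len(self.traits) else None

    def lambda_mask(self) -> np.ndarray:
        """Boolean (t, t) mask of free Lambda entries (row = child)."""
        m = np.zeros((self.t, self.t), dtype=bool)
        for p, c in self.edges:
            m[self.index(c), self.index(p)] = True
        return m

    def lambda_from_edge_values(self, values: dict[tuple[str, str], float]) -> np.ndarray:
        lam = np.zeros((self.t, self.t))
        for (p, c), v in values.items():
            if (p, c) not in self.edges:
                raise StructureError(f"({p!r}, {c!r}) is not an edge of the structure")
            lam[self.index(c), self.index(p)] = v
        return lam

    @classmethod
    def fully_recursive(cls, traits) -> "CausalStructure":
        """All lower-triangular entries free under the declared trait order."""
        traits = tuple(traits)
        edges = {
            (traits[j], traits[i]) for i in range(len(traits)) for j in range(i)
        }
        return cls(traits=traits, edges=frozenset(edges))

    @classmethod
    def empty(cls, traits) -> "CausalStructure":
        return cls(traits=tuple(traits), edges=frozenset())

    # -- serialization ------------------------------------------------------

    def to_edge_list(self) -> str:
        lines = [f"# traits: {','.join(self.traits)}"]
        lines += [f"{p} -> {c}" for p, c in sorted(self.edges)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list(cls, text: str) -> "CausalStructure":
        traits: tuple[str, ...] | None = None
        edges = set()
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "traits:" in line:
                    traits = tuple(
                        s.strip() for s in line.split("traits:", 1)[1].split(",")
                    )
                continue
            p, c = (s.strip() for s in line.split("->"))
            edges.add((p, c))
        if traits is None:
            raise StructureError("edge-list text lacks a '# traits:' header")
        return cls(traits=traits, edges=frozenset(edges))

    def to_dot(self) -> str:
        lines = ["digraph causal_structure {"]
        for t in self.traits:
            lines.append(f'  "{t}";')
        for p, c in sorted(self.edges):
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class SEMParameters:
    """One full parameter set of a recursive SEM.

    ``lam`` is (t, t) with row = affected trait; ``beta`` is (t, n_seasons);
    ``u`` is (n_animals, t) aligned to some animal indexing the caller
    controls; ``g0`` (t, t) genetic covariance; ``psi`` length-t residual
    variances.
    """

    structure: CausalStructure
    lam: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    g0: np.ndarray
    psi: np.ndarray

    def validate(self) -> None:
        t = self.structure.t
        mask = self.structure.lambda_mask()
        if self.lam.shape != (t, t):
            raise ValueError("Lambda shape mismatch")
        if np.any(self.lam[~mask] != 0.0):
            raise ValueError("Lambda nonzero outside the structure's edges")
        if np.any(self.psi <= 0):
            raise ValueError("residual variances must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "traits": list(self.structure.traits),
                "edges": sorted(list(e) for e in self.structure.edges),
                "lambda": self.lam.tolist(),
                "beta": self.beta.tolist(),
                "g0": self.g0.tolist(),
                "psi": self.psi.tolist(),
            },
            indent=1,
        )


@dataclass(frozen=True)
class ReducedDispersion:
    """SEM dispersion parameters mapped to the MTAM scale."""

    r0_star: np.ndarray
    g0_star: np.ndarray

    @property
    def heritabilities(self) -> np.ndarray:
        return heritabilities(self.g0_star, self.r0_star)


# ---------------------------------------------------------------------------
# reduction algebra

def _check_square(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    return m


def reduce_residual_covariance(lam: np.ndarray, psi) -> np.ndarray:
    """MTAM-scale residual covariance R0* = (I-Lambda)^-1 Psi0 (I-Lambda)^-T.

    ``psi`` may be a length-t vector of residual variances or a diagonal
    matrix.  Acyclicity makes (I - Lambda) unit-triangular under some trait
    permutation, hence always invertible.
    """
    lam = _check_square(lam, "Lambda")
    psi = np.asarray(psi, dtype=float)
    if psi.ndim == 1:
        psi = np.diag(psi)
    L = np.linalg.inv(np.eye(lam.shape[0]) - lam)
    return L @ psi @ L.T


def reduce_genetic_covariance(lam: np.ndarray, g0: np.ndarray) -> np.ndarray:
    """MTAM-scale genetic covariance G0* = (I-Lambda)^-1 G0 (I-Lambda)^-T."""
    lam = _check_square(lam, "Lambda")
    g0 = _check_square(g0, "G0")
    L = np.linalg.inv(np.eye(lam.shape[0]) - lam)
    return L @ g0 @ L.T


def reduce_dispersion(lam: np.ndarray, g0: np.ndarray, psi) -> ReducedDispersion:
    return ReducedDispersion(
        r0_star=reduce_residual_covariance(lam, psi),
        g0_star=reduce_genetic_covariance(lam, g0),
    )


def heritabilities(g0_star: np.ndarray, r0_star: np.ndarray) -> np.ndarray:
    """h_j^2 = g*_jj / (g*_jj + r*_jj), the reduced-scale heritabilities."""
    g = np.diag(np.asarray(g0_star, dtype=float))
    r = np.diag(np.asarray(r0_star, dtype=float))
    tot = g + r
    if np.any(tot <= 0):
        raise ValueError("zero total variance for at least one trait")
    return g / tot


def correlation_from_covariance(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# conditional likelihood  (Gaussian, per-animal blocks)

def conditional_log_likelihood(
    y: np.ndarray,
    season: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    u: np.ndarray,
    psi: np.ndarray,
) -> float:
    """Log p(y | Lambda, beta, u, Psi0), in nats.

    The phenotypes of animal ``i`` are multivariate normal with mean
    ``(I-Lambda)^-1 (beta[:, season_i] + u_i)`` and covariance
    ``R0* = (I-Lambda)^-1 Psi0 (I-Lambda)^-T``; residual independence
    across animals lets the density factorize into t x t blocks, so the
    tn x tn covariance is never materialized.

    Parameters
    ----------
    y : (n, t) phenotypes
    season : (n,) integer season codes indexing beta's columns
    lam : (t, t) structural coefficients, row = affected trait
    beta : (t, n_seasons) season effects
    u : (n, t) additive genetic effects of the phenotyped animals
    psi : (t,) residual variances
    """
    y = np.asarray(y, dtype=float)
    n, t = y.shape
    lam = _check_square(lam, "Lambda")
    psi = np.asarray(psi, dtype=float)
    L = np.linalg.inv(np.eye(t) - lam)
    r_star = L @ np.diag(psi) @ L.T
    try:
        chol = np.linalg.cholesky(r_star)
    except np.linalg.LinAlgError as exc:
        raise ValueError("reduced residual covariance is not positive definite") from exc
    mean = (beta[:, season].T + u) @ L.T          # (n, t)
    resid = y - mean
    w = solve_triangular(chol, resid.T, lower=True)
    quad = float(np.sum(w * w))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (n * t * np.log(2.0 * np.pi) + n * logdet + quad)


def structural_log_likelihood(
    y: np.ndarray,
    season: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    u: np.ndarray,
    psi: np.ndarray,
) -> float:
    """Same density evaluated on the structural scale.

    ``e_i = (I-Lambda) y_i - beta[:, season_i] - u_i`` has independent
    components with variances ``psi``; the transform ``I-Lambda`` has unit
    determinant (acyclic structure), so no Jacobian term appears.  Agrees
    with :func:`conditional_log_likelihood` to numerical precision and is
    the cheap form the sampler uses for per-draw deviances.
    """
    y = np.asarray(y, dtype=float)
    n, t = y.shape
    e = y @ (np.eye(t) - lam).T - beta[:, season].T - u
    quad = np.sum(e * e / psi, axis=0)
    return float(-0.5 * (n * t * np.log(2.0 * np.pi) + n * np.sum(np.log(psi)) + np.sum(quad)))


# ---------------------------------------------------------------------------
# MTAM <-> fully recursive mapping (likelihood equivalence)

def mtam_to_fully_recursive(r0_mtam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map an MTAM residual covariance to fully recursive (Lambda, Psi0).

    Under the declared trait order, LDL-factorize ``R0 = L D L'`` with L
    unit lower triangular; then ``(I - Lambda)^-1 = L`` and ``Psi0 = D``.
    The resulting fully recursive SEM reproduces the MTAM likelihood
    exactly (triangular systems are just a reparameterization).
    """
    r0 = _check_square(r0_mtam, "R0")
    c = np.linalg.cholesky(r0)
    d_sqrt = np.diag(c)
    L = c / d_sqrt[np.newaxis, :]
    lam = np.eye(r0.shape[0]) - np.linalg.inv(L)
    return lam, d_sqrt**2
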