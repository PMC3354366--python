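"""Gibbs sampling for recursive mixed-effects SEMs.

Every full conditional is conjugate: with flat priors on season effects and
structural coefficients, each trait's (beta_j, lambda_j.) block is a normal
linear-model draw; the additive genetic effects u are updated per animal in
t-dimensional blocks exploiting the sparsity of the pedigree relationship
inverse; G0 gets an inverse-Wishart draw and each residual variance psi_j a
scaled inverse-chi-square draw.  The fully recursive fit doubles as the
multiple-trait animal model (MTAM): its per-draw reduced residual
covariance R0* is the input to the causal-structure search.

Default hyperparameters and chain settings follow a quail layer analysis:
residual prior scales s^2 = (0.6, 400, 70, 0.7, 40) with 3 df, genetic
prior scale diag(0.3, 200, 30, 0.3, 10) with 7 df, and a single chain of
300,000 iterations discarding 100,000 as burn-in; a much smaller test
profile is provided for synthetic-data work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import invwishart

from .pedigree import a_inverse
from .sem import (
    CausalStructure,
    reduce_genetic_covariance,
    reduce_residual_covariance,
)
from .simulate import Dataset


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters: IW(nu_g, g0_scale) on G0, scaled-inv-chi2
    (nu_psi, s2_j) on each residual variance, flat on beta and Lambda."""

    nu_g: float = 7.0
    g0_scale: np.ndarray = field(
        default_factory=lambda: np.diag([0.3, 200.0, 30.0, 0.3, 10.0])
    )
    nu_psi: float = 3.0
    s2: np.ndarray = field(
        default_factory=lambda: np.array([0.6, 400.0, 70.0, 0.7, 40.0])
    )

    def validate(self, t: int) -> None:
        g = np.asarray(self.g0_scale, dtype=float)
        s = np.asarray(self.s2, dtype=float)
        if g.shape != (t, t):
            raise FitError(f"g0_scale must be {t}x{t}")
        if self.nu_g <= t - 1:
            raise FitError("nu_g must exceed t - 1")
        if s.shape != (t,) or np.any(s <= 0):
            raise FitError("s2 must be a positive length-t vector")
        if np.any(np.diag(g) <= 0):
            raise FitError("g0_scale diagonal must be positive")

    @classmethod
    def for_traits(cls, t: int) -> "Hyperparameters":
        """Defaults for an arbitrary trait count (5-trait values otherwise)."""
        if t == 5:
            return cls()
        return cls(
            nu_g=t + 2.0,
            g0_scale=np.eye(t),
            nu_psi=3.0,
            s2=np.ones(t),
        )


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 300_000
    burn_in: int = 100_000
    thin: int = 1
    seed: int = 1

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise FitError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise FitError("thinning interval must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: small profile for synthetic-data testing
TEST_PROFILE = McmcSettings(iterations=5_000, burn_in=2_000, thin=1, seed=1)


@dataclass
class ParamSummary:
    mean: float
    sd: float
    hpd_lower: float
    hpd_upper: float
    content: float


@dataclass
class PosteriorChain:
    """Retained draws of a recursive-SEM Gibbs chain.

    ``u_mean`` is the running mean of the genetic effects over retained
    draws (full u chains are not stored); ``r0_star`` holds the per-draw
    reduced residual covariance, ``deviance`` the per-draw conditional
    deviance -2 log p(y | Lambda, beta, u, Psi0).
    """

    structure: CausalStructure
    lam: np.ndarray        # (m, t, t)
    beta: np.ndarray       # (m, t, S)
    g0: np.ndarray         # (m, t, t)
    psi: np.ndarray        # (m, t)
    r0_star: np.ndarray    # (m, t, t)
    deviance: np.ndarray   # (m,)
    u_mean: np.ndarray     # (q, t)
    settings: McmcSettings
    hyper: Hyperparameters

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    @property
    def traits(self) -> tuple[str, ...]:
        return self.structure.traits

    def g0_star(self) -> np.ndarray:
        """Per-draw reduced-scale genetic covariance (m, t, t)."""
        return np.stack(
            [reduce_genetic_covariance(l, g) for l, g in zip(self.lam, self.g0)]
        )

    def heritability_draws(self) -> np.ndarray:
        gs = self.g0_star()
        g = np.diagonal(gs, axis1=1, axis2=2)
        r = np.diagonal(self.r0_star, axis1=1, axis2=2)
        return g / (g + r)

    def samples(self, selector: str) -> np.ndarray:
        """1-D sample vector for a named scalar parameter.

        Selectors: ``lambda:P->C``, ``beta:TRAIT,s``, ``psi:TRAIT``,
        ``g0:TRAIT,TRAIT``, ``r0_star:TRAIT,TRAIT``, ``g0_star:TRAIT,TRAIT``,
        ``h2:TRAIT``, ``deviance``.
        """
        if not selector:
            raise ValueError("empty parameter selector")
        traits = self.traits
        kind, _, rest = selector.partition(":")
        if kind == "deviance":
            return self.deviance
        if kind == "lambda":
            p, c = (s.strip() for s in rest.split("->"))
            return self.lam[:, traits.index(c), traits.index(p)]
        if kind == "psi":
            return self.psi[:, traits.index(rest.strip())]
        if kind == "h2":
            return self.heritability_draws()[:, traits.index(rest.strip())]
        if kind in ("g0", "r0_star", "g0_star"):
            a, b = (s.strip() for s in rest.split(","))
            arr = {
                "g0": self.g0,
                "r0_star": self.r0_star,
                "g0_star": self.g0_star(),
            }[kind]
            return arr[:, traits.index(a), traits.index(b)]
        if kind == "beta":
            tr, s = (x.strip() for x in rest.split(","))
            return self.beta[:, traits.index(tr), int(s)]
        raise ValueError(f"unknown selector {selector!r}")


def posterior_summary(
    chain: PosteriorChain, selector: str, content: float = 0.95
) -> ParamSummary:
    """Posterior mean, SD and HPD interval for one scalar parameter."""
    from .search import hpd_interval

    x = chain.samples(selector)
    lo, hi = hpd_interval(x, content)
    return ParamSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        hpd_lower=lo,
        hpd_upper=hi,
        content=content,
    )


# ---------------------------------------------------------------------------
# the per-animal u sweep (sequential scan; JIT-compiled when numba is there)

def _u_sweep_py(u, Z, aii, ptr, idx, val, data_row, D, ginv, psiinv):
    """Sequential per-animal block draw of u; updates ``u`` in place.

    For animal i the full conditional is N(P^-1 r, P^-1) with
    P = a^{ii} G0^-1 (+ diag(1/psi) if phenotyped) and
    r = -G0^-1 sum_{k != i} a^{ik} u_k (+ d_i / psi); the draw is
    mean + L^-T z with P = L L'.
    """
    q, t = u.shape
    for i in range(q):
        lo, hi = ptr[i], ptr[i + 1]
        svec = np.zeros(t)
        for n in range(lo, hi):
            k = idx[n]
            v = val[n]
            for j in range(t):
                svec[j] += v * u[k, j]
        rhs = -(ginv @ svec)
        prec = aii[i] * ginv
        r = data_row[i]
        if r >= 0:
            prec = prec.copy()
            for j in range(t):
                rhs[j] += psiinv[j] * D[r, j]
                prec[j, j] += psiinv[j]
        L = np.linalg.cholesky(prec)
        # mean: solve L w = rhs, then L' m = w
        w = np.zeros(t)
        for j in range(t):
            s = rhs[j]
            for k in range(j):
                s -= L[j, k] * w[k]
            w[j] = s / L[j, j]
        mean = np.zeros(t)
        for j in range(t - 1, -1, -1):
            s = w[j]
            for k in range(j + 1, t):
                s -= L[k, j] * mean[k]
            mean[j] = s / L[j, j]
        # noise: solve L' x = z  ->  cov(x) = P^-1
        x = np.zeros(t)
        for j in range(t - 1, -1, -1):
            s = Z[i, j]
            for k in range(j + 1, t):
                s -= L[k, j] * x[k]
            x[j] = s / L[j, j]
        for j in range(t):
            u[i, j] = mean[j] + x[j]


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _u_sweep = njit(cache=True)(_u_sweep_py)
except ImportError:  # pragma: no cover
    _u_sweep = _u_sweep_py


# ---------------------------------------------------------------------------
# the sampler

class GibbsSampler:
    """Gibbs machinery for one dataset + causal structure.

    Step methods implement the individual full conditionals so they can be
    exercised separately (e.g. by successive-conditional validity checks);
    :func:`fit_sem` drives the usual cycle.
    """

    def __init__(
        self,
        dataset: Dataset,
        structure: CausalStructure,
        hyper: Hyperparameters,
        rng: np.random.Generator,
    ):
        self.structure = structure
        self.hyper = hyper
        self.rng = rng
        self.traits = structure.traits
        self.t = structure.t
        self.y = dataset.y()
        self.n = self.y.shape[0]
        self.season = dataset.season()
        self.n_seasons = int(self.season.max()) + 1
        self.rows = dataset.animal_rows()
        self.q = len(dataset.pedigree)
        hyper.validate(self.t)

        counts = np.bincount(self.season, minlength=self.n_seasons)
        if np.any(counts == 0):
            empty = np.where(counts == 0)[0]
            raise FitError(f"empty hatch-season class(es): {empty.tolist()}")

        # per-trait fixed design: season dummies then parents' phenotypes
        self.parent_cols: list[np.ndarray] = []
        self.design: list[np.ndarray] = []
        self.design_chol = []
        S = self.n_seasons
        dummies = np.zeros((self.n, S))
        dummies[np.arange(self.n), self.season] = 1.0
        for j, tr in enumerate(self.traits):
            pars = structure.parents(tr)
            pcols = np.array([self.traits.index(p) for p in pars], dtype=np.int64)
            X = np.hstack([dummies, self.y[:, pcols]]) if len(pcols) else dummies
            xtx = X.T @ X
            try:
                c = cho_factor(xtx)
            except np.linalg.LinAlgError as exc:
                raise FitError(
                    f"non-estimable fixed-effect/structural design for trait {tr}"
                ) from exc
            self.parent_cols.append(pcols)
            self.design.append(X)
            self.design_chol.append(c)

        # pedigree precision structure: diagonal + off-diagonal CSR
        ainv = a_inverse(dataset.pedigree).tocsr()
        self.ainv = ainv
        self.aii = ainv.diagonal().copy()
        off = ainv - sp.diags(self.aii)
        off.eliminate_zeros()
        off = off.tocsr()
        self.nbr_ptr = off.indptr
        self.nbr_idx = off.indices
        self.nbr_val = off.data

        self.is_pheno = np.zeros(self.q, dtype=bool)
        self.is_pheno[self.rows] = True
        self.data_row = np.full(self.q, -1, dtype=np.int64)
        self.data_row[self.rows] = np.arange(self.n)

        # state
        self.lam = np.zeros((self.t, self.t))
        self.beta = np.zeros((self.t, S))
        for j in range(self.t):
            for s in range(S):
                self.beta[j, s] = self.y[self.season == s, j].mean()
        self.u = np.zeros((self.q, self.t))
        self.g0 = np.asarray(hyper.g0_scale, dtype=float).copy()
        self.psi = np.asarray(hyper.s2, dtype=float).copy()

    # -- full conditionals --------------------------------------------------

    def step_coefficients(self) -> None:
        """Draw (beta_j, lambda_j.) jointly per trait under flat priors."""
        S = self.n_seasons
        for j in range(self.t):
            X = self.design[j]
            r = self.y[:, j] - self.u[self.rows, j]
            mean = cho_solve(self.design_chol[j], X.T @ r)
            z = self.rng.standard_normal(X.shape[1])
            c, lower = self.design_chol[j]
            # theta = mean + sqrt(psi_j) * chol(XtX)^-T z
            dev = cho_solve_upper(c, z, lower)
            theta = mean + np.sqrt(self.psi[j]) * dev
            self.beta[j, :] = theta[:S]
            if len(self.parent_cols[j]):
                self.lam[j, self.parent_cols[j]] = theta[S:]

    def step_u(self) -> None:
        """Per-animal block update of the genetic effects.

        Conditional of u_i given the rest:  precision
        a^{ii} G0^-1 (+ Psi0^-1 if phenotyped), precision-weighted mean
        -G0^-1 sum_k a^{ik} u_k (+ Psi0^-1 d_i), where
        d_i = (I-Lambda) y_i - beta[:, season_i].
        """
        ginv = np.linalg.inv(self.g0)
        psiinv = 1.0 / self.psi
        D = self.y @ (np.eye(self.t) - self.lam).T - self.beta[:, self.season].T
        Z = self.rng.standard_normal((self.q, self.t))
        _u_sweep(
            self.u,
            Z,
            self.aii,
            self.nbr_ptr,
            self.nbr_idx,
            self.nbr_val,
            self.data_row,
            D,
            ginv,
            psiinv,
        )

    def step_g0(self) -> None:
        """G0 | u  ~  IW(nu_g + q, g0_scale + U' A^-1 U)."""
        scale = np.asarray(self.hyper.g0_scale, dtype=float) + self.u.T @ (
            self.ainv @ self.u
        )
        scale = 0.5 * (scale + scale.T)
        draw = invwishart.rvs(
            df=self.hyper.nu_g + self.q, scale=scale, random_state=self.rng
        )
        self.g0 = np.atleast_2d(draw)  # scipy returns a scalar when t = 1

    def step_psi(self) -> None:
        """psi_j | .  ~  scaled-inv-chi2(nu_psi + n, conjugate scale)."""
        e = self._residuals()
        sse = np.sum(e * e, axis=0)
        df = self.hyper.nu_psi + self.n
        num = self.hyper.nu_psi * np.asarray(self.hyper.s2) + sse
        self.psi = num / self.rng.chisquare(df, size=self.t)

    def _residuals(self) -> np.ndarray:
        """(n, t) structural residuals e = (I-Lambda) y - X beta - u."""
        return (
            self.y @ (np.eye(self.t) - self.lam).T
            - self.beta[:, self.season].T
            - self.u[self.rows]
        )

    def deviance(self) -> float:
        """-2 log p(y | Lambda, beta, u, Psi0) at the current state."""
        e = self._residuals()
        quad = np.sum(e * e / self.psi)
        return float(
            self.n * self.t * np.log(2.0 * np.pi)
            + self.n * np.sum(np.log(self.psi))
            + quad
        )

    def simulate_y(self) -> np.ndarray:
        """Draw phenotypes from the model at the current parameters
        (used by successive-conditional validity checks)."""
        e = self.rng.standard_normal((self.n, self.t)) * np.sqrt(self.psi)
        L = np.linalg.inv(np.eye(self.t) - self.lam)
        return (self.beta[:, self.season].T + self.u[self.rows] + e) @ L.T

    def set_y(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float)
        # refresh the structural columns of the per-trait designs
        S = self.n_seasons
        for j in range(self.t):
            pcols = self.parent_cols[j]
            if len(pcols):
                X = self.design[j]
                X[:, S:] = self.y[:, pcols]
                self.design_chol[j] = cho_factor(X.T @ X)

    def cycle(self) -> None:
        self.step_coefficients()
        self.step_u()
        self.step_g0()
        self.step_psi()


def cho_solve_upper(c: np.ndarray, z: np.ndarray, lower: bool) -> np.ndarray:
    """Solve R' x = z where c is the Cholesky factor from cho_factor.

    cho_factor returns the upper factor R (xtx = R'R) when lower=False; the
    coefficient draw needs R^-1 z so that cov(x) = (R'R)^-1.
    """
    from scipy.linalg import solve_triangular

    if lower:
        return solve_triangular(c.T, z, lower=False)
    return solve_triangular(c, z, lower=False)


def fit_sem(
    dataset: Dataset,
    structure: CausalStructure,
    hyper: Hyperparameters | None = None,
    settings: McmcSettings = TEST_PROFILE,
) -> PosteriorChain:
    """Fit a recursive SEM by Gibbs sampling; deterministic given the seed."""
    hyper = hyper if hyper is not None else Hyperparameters.for_traits(structure.t)
    rng = np.random.default_rng(settings.seed)
    smp = GibbsSampler(dataset, structure, hyper, rng)
    m = settings.n_draws
    t, S = smp.t, smp.n_seasons
    lam = np.empty((m, t, t))
    beta = np.empty((m, t, S))
    g0 = np.empty((m, t, t))
    psi = np.empty((m, t))
    r0s = np.empty((m, t, t))
    dev = np.empty(m)
    u_mean = np.zeros((smp.q, t))
    k = 0
    for it in range(settings.iterations):
        smp.cycle()
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if k < m:
                lam[k] = smp.lam
                beta[k] = smp.beta
                g0[k] = smp.g0
                psi[k] = smp.psi
                r0s[k] = reduce_residual_covariance(smp.lam, smp.psi)
                dev[k] = smp.deviance()
                u_mean += smp.u
                k += 1
    u_mean /= max(k, 1)
    return PosteriorChain(
        structure=structure,
        lam=lam[:k],
        beta=beta[:k],
        g0=g0[:k],
        psi=psi[:k],
        r0_star=r0s[:k],
        deviance=dev[:k],
        u_mean=u_mean,
        settings=settings,
        hyper=hyper,
    )


def fit_fully_recursive(
    dataset: Dataset,
    hyper: Hyperparameters | None = None,
    settings: McmcSettings = TEST_PROFILE,
) -> PosteriorChain:
    """Fit the fully recursive SEM (all lower-triangular Lambda entries
    free), whose reduced dispersion reproduces the MTAM: the stored R0*
    draws are the causal search's input."""
    structure = CausalStructure.fully_recursive(dataset.traits)
    return fit_sem(dataset, structure, hyper, settings)
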