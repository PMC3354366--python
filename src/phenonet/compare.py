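"""Conditional deviance and DIC for fitted recursive SEMs.

The deviance is D(theta) = -2 log p(y | Lambda, beta, u, Psi0), i.e. it
conditions on the genetic effects, and theta-bar includes the posterior
mean of u.  DIC = 2 D-bar - D(theta-bar); the effective parameter count is
pD = D-bar - D(theta-bar).  Lower DIC indicates a better fit-complexity
trade-off; SEMs whose causal structures come from different equivalence
classes (and the unrestricted MTAM) are comparable this way, while
structures within one class are likelihood-equivalent and are not.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .gibbs import PosteriorChain
from .sem import SEMParameters, structural_log_likelihood
from .simulate import Dataset


class ComparisonError(ValueError):
    pass


def dataset_key(dataset: Dataset) -> str:
    """Stable fingerprint used to refuse cross-dataset DIC comparisons."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.y()).tobytes())
    h.update(np.ascontiguousarray(dataset.season()).tobytes())
    return h.hexdigest()[:16]


def deviance(dataset: Dataset, params: SEMParameters) -> float:
    """-2 x conditional log-likelihood at one parameter set.

    ``params.u`` must be aligned to the dataset's pedigree rows; only the
    phenotyped animals' rows enter the likelihood.
    """
    rows = dataset.animal_rows()
    ll = structural_log_likelihood(
        dataset.y(),
        dataset.season(),
        params.lam,
        params.beta,
        params.u[rows],
        params.psi,
    )
    return -2.0 * ll


@dataclass(frozen=True)
class DICResult:
    """Deviance summaries for one fitted model on one dataset."""

    model: str
    dbar: float
    d_at_mean: float
    dataset: str

    @property
    def dic(self) -> float:
        return 2.0 * self.dbar - self.d_at_mean

    @property
    def p_d(self) -> float:
        return self.dbar - self.d_at_mean


def dic(chain: PosteriorChain, dataset: Dataset, model: str = "model") -> DICResult:
    """DIC from a chain's stored per-draw deviances and running u mean."""
    if chain.deviance.size == 0:
        raise ComparisonError("chain stores no deviance draws")
    if chain.u_mean is None or not np.any(np.isfinite(chain.u_mean)):
        raise ComparisonError("chain stores no posterior mean of u")
    params = SEMParameters(
        structure=chain.structure,
        lam=chain.lam.mean(axis=0),
        beta=chain.beta.mean(axis=0),
        u=chain.u_mean,
        g0=chain.g0.mean(axis=0),
        psi=chain.psi.mean(axis=0),
    )
    d_mean = deviance(dataset, params)
    result = DICResult(
        model=model,
        dbar=float(chain.deviance.mean()),
        d_at_mean=d_mean,
        dataset=dataset_key(dataset),
    )
    return result


@dataclass
class ComparisonReport:
    ranked: list[DICResult]
    deltas: list[float]
    notes: list[str]

    def to_text(self) -> str:
        lines = [f"{'model':<20}{'DIC':>12}{'Dbar':>12}{'pD':>10}{'delta':>10}"]
        for res, d in zip(self.ranked, self.deltas):
            lines.append(
                f"{res.model:<20}{res.dic:>12.2f}{res.dbar:>12.2f}"
                f"{res.p_d:>10.2f}{d:>10.2f}"
            )
        lines.extend(self.notes)
        return "\n".join(lines)

    def best(self) -> DICResult:
        return self.ranked[0]


def compare(results: list[DICResult], equivalence_margin: float = 2.0) -> ComparisonReport:
    """Rank models by DIC with deltas to the best.

    Models must have been fitted to the same dataset; pairs within
    ``equivalence_margin`` of the best are flagged as practically
    equivalent rather than distinguished.
    """
    if len(results) < 2:
        raise ComparisonError("need at least 2 models to compare")
    keys = {r.dataset for r in results}
    if len(keys) != 1:
        raise ComparisonError("DIC results come from different datasets")
    ranked = sorted(results, key=lambda r: r.dic)
    best = ranked[0].dic
    deltas = [r.dic - best for r in ranked]
    notes = []
    near = [r.model for r, d in zip(ranked[1:], deltas[1:]) if d < equivalence_margin]
    if near:
        notes.append(
            f"note: {', '.join(near)} within {equivalence_margin} DIC of the "
            f"best ({ranked[0].model}); treat as practically equivalent"
        )
    ties = [
        r.model for r, d in zip(ranked[1:], deltas[1:]) if d == 0.0
    ]
    if ties:
        notes.append(f"note: exact DIC tie between {ranked[0].model} and {', '.join(ties)}")
    return ComparisonReport(ranked=ranked, deltas=deltas, notes=notes)
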