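"""Synthetic pedigreed multi-trait data with known causal ground truth.

Generates exactly the statistical structure the analysis assumes: a
multi-generation pedigree, additive genetic effects with covariance
``G0 (x) A`` (drawn by sequential Mendelian sampling, which is exact and
O(q t^2)), fixed hatch-season effects, and phenotypes from a recursive SEM
with diagonal residual covariance under a configurable causal structure.
The ``paper_model_C`` preset emulates a quail layer study: five traits —
birth weight (BW, g), 35-day weight (W35, g), age at first egg (AFE, d),
average egg weight (AEW, g) and number of eggs (NE) — six hatch seasons,
and the causal graph BW->AEW, W35->AFE->NE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import (
    Pedigree,
    inbreeding_coefficients,
    relationship_matrix,
    validate_and_sort,
    write_pedigree,
)
from .sem import CausalStructure

#: canonical trait order; all tables and Lambda conventions follow it
TRAITS: tuple[str, ...] = ("BW", "W35", "AFE", "AEW", "NE")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class PedigreePlan:
    """Breeding design: founders, then per-generation random mating."""

    n_founders: int = 150
    n_generations: int = 5
    n_matings: int = 60
    n_offspring: int = 4

    @property
    def n_total(self) -> int:
        return self.n_founders + self.n_generations * self.n_matings * self.n_offspring


@dataclass(frozen=True)
class SimulationScenario:
    """Complete generating model for one synthetic dataset."""

    plan: PedigreePlan
    structure: CausalStructure
    lambda_values: tuple[tuple[str, str, float], ...]  # (parent, child, coeff)
    g0: np.ndarray                      # (t, t) genetic covariance
    psi: np.ndarray                     # (t,) residual variances
    beta: np.ndarray                    # (t, n_seasons) season effects
    n_phenotyped: int = 0               # 0 = all non-founders
    n_seasons: int = 6
    seed: int = 20110037

    def __post_init__(self):
        g0 = np.asarray(self.g0, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "g0", g0)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "beta", beta)
        t = self.structure.t
        if g0.shape != (t, t) or not np.allclose(g0, g0.T):
            raise ScenarioError("G0 must be symmetric t x t")
        if np.any(np.linalg.eigvalsh(g0) < -1e-8 * max(1.0, np.abs(g0).max())):
            raise ScenarioError("G0 must be positive semi-definite")
        if psi.shape != (t,) or np.any(psi <= 0):
            raise ScenarioError("Psi0 must be a length-t vector of positive variances")
        if beta.shape != (t, self.n_seasons):
            raise ScenarioError("beta must be (t, n_seasons)")
        for p, c, _ in self.lambda_values:
            if (p, c) not in self.structure.edges:
                raise ScenarioError(f"lambda value for non-edge ({p!r}, {c!r})")

    @property
    def traits(self) -> tuple[str, ...]:
        return self.structure.traits

    def lambda_matrix(self) -> np.ndarray:
        return self.structure.lambda_from_edge_values(
            {(p, c): v for p, c, v in self.lambda_values}
        )


@dataclass
class Dataset:
    """Simulated phenotypes plus everything needed to score an analysis."""

    phenotypes: pd.DataFrame            # animal, season, one column per trait
    pedigree: Pedigree
    traits: tuple[str, ...]
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def y(self) -> np.ndarray:
        return self.phenotypes[list(self.traits)].to_numpy(dtype=float)

    def season(self) -> np.ndarray:
        return self.phenotypes["season"].to_numpy(dtype=np.int64)

    def animal_rows(self) -> np.ndarray:
        """Pedigree row index of each phenotyped animal."""
        return np.array(
            [self.pedigree.index_of(a) for a in self.phenotypes["animal"]],
            dtype=np.int64,
        )


# ---------------------------------------------------------------------------
# pedigree simulation

def simulate_pedigree(plan: PedigreePlan, seed: int) -> Pedigree:
    """Multi-generation pedigree by random mating within the previous cohort.

    Sexes alternate within each cohort (even index male, odd female), so a
    cohort of >= 2 always contains both sexes and selfing is impossible;
    randomness (seeded) enters only through mate choice.
    """
    if plan.n_founders < 2:
        raise ScenarioError("need at least 2 founders to avoid selfing")
    if plan.n_generations > 0:
        if plan.n_matings < 1 or plan.n_offspring < 1:
            raise ScenarioError("matings and offspring counts must be positive")
        if plan.n_matings * plan.n_offspring < 2 and plan.n_generations > 1:
            raise ScenarioError("cohort of one animal cannot reproduce further")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str | None, str | None]] = []
    cohort = [f"G0_{i:04d}" for i in range(plan.n_founders)]
    records += [(a, None, None) for a in cohort]
    for g in range(1, plan.n_generations + 1):
        males = cohort[0::2]
        females = cohort[1::2]
        if not males or not females:
            raise ScenarioError(f"generation {g - 1} lacks one sex entirely")
        new: list[str] = []
        for m in range(plan.n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for k in range(plan.n_offspring):
                a = f"G{g}_{m:03d}_{k:02d}"
                records.append((a, sire, dam))
                new.append(a)
        cohort = new
    return validate_and_sort(records)


# ---------------------------------------------------------------------------
# genetic effects:  u ~ N(0, G0 (x) A) by sequential Mendelian sampling

def _psd_factor(g0: np.ndarray) -> np.ndarray:
    """Factor B with B B' = G0, valid for singular G0."""
    w, v = np.linalg.eigh(g0)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_genetic_effects(
    pedigree: Pedigree, g0: np.ndarray, seed_or_rng
) -> np.ndarray:
    """One (q, t) draw of additive genetic effects with covariance G0 (x) A.

    Founders draw N(0, G0); a non-founder gets the mean of its known
    parents' values plus a Mendelian-sampling deviation scaled by the
    parents' inbreeding:  variance ``G0 (0.5 - 0.25 (F_s + F_d))`` with both
    parents known, ``G0 (0.75 - 0.25 F_p)`` with one, G0 for neither.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    g0 = np.asarray(g0, dtype=float)
    t = g0.shape[0]
    q = len(pedigree)
    par = pedigree.parent_indices()
    F = inbreeding_coefficients(pedigree)
    B = _psd_factor(g0)
    z = rng.standard_normal((q, t))
    u = np.zeros((q, t))
    for i in range(q):
        s, d = par[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            scale = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mean = 0.5 * u[p]
            scale = 0.75 - 0.25 * F[p]
        else:
            mean = 0.0
            scale = 1.0
        u[i] = mean + np.sqrt(scale) * (B @ z[i])
    return u


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(
    pedigree: Pedigree, scenario: SimulationScenario
) -> Dataset:
    """Reduced-model phenotypes  y = (I-Lambda)^-1 (X beta + Z u + e).

    Residuals are independent across traits (diagonal Psi0) and animals;
    hatch seasons are assigned uniformly at random to the phenotyped
    animals (the most recent ``n_phenotyped`` in pedigree order; 0 means
    all non-founders).  Everything is recorded in ``truth``.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    t = scenario.structure.t
    lam = scenario.lambda_matrix()
    u = simulate_genetic_effects(pedigree, scenario.g0, rng)

    n_pheno = scenario.n_phenotyped or (
        len(pedigree) - sum(1 for _, s, d in pedigree.records if s is None and d is None)
    )
    n_pheno = min(n_pheno, len(pedigree))
    rows = np.arange(len(pedigree) - n_pheno, len(pedigree))
    ids = [pedigree.records[i][0] for i in rows]

    season = rng.integers(scenario.n_seasons, size=n_pheno)
    e = rng.standard_normal((n_pheno, t)) * np.sqrt(scenario.psi)
    L = np.linalg.inv(np.eye(t) - lam)
    y = (scenario.beta[:, season].T + u[rows] + e) @ L.T

    phen = pd.DataFrame({"animal": ids, "season": season})
    for j, tr in enumerate(scenario.traits):
        phen[tr] = y[:, j]
    truth = {
        "scenario": scenario,
        "u": u,
        "e": e,
        "rows": rows,
        "lambda": lam,
    }
    return Dataset(
        phenotypes=phen, pedigree=pedigree, traits=scenario.traits, truth=truth
    )


def simulate_dataset(scenario: SimulationScenario) -> Dataset:
    """Pedigree + phenotypes in one call, fully determined by the scenario."""
    ped = simulate_pedigree(scenario.plan, scenario.seed)
    return simulate_phenotypes(ped, scenario)


# ---------------------------------------------------------------------------
# presets

#: Model C structural coefficients (posterior means): day/g, egg/day, g/g
_MODEL_C_LAMBDA = (
    ("W35", "AFE", -0.052),
    ("AFE", "NE", -0.113),
    ("BW", "AEW", -0.408),
)

#: Model C residual variances per trait (g^2, g^2, d^2, g^2, egg^2)
_MODEL_C_PSI = np.array([0.33, 195.78, 34.65, 0.68, 30.62])

#: Model C genetic variances and correlations
_MODEL_C_GVAR = np.array([0.45, 185.36, 14.09, 0.89, 5.19])
_MODEL_C_GCORR = {
    (0, 1): 0.45, (0, 2): 0.21, (0, 3): 0.80, (0, 4): 0.07,
    (1, 2): 0.21, (1, 3): 0.58, (1, 4): 0.19,
    (2, 3): 0.16, (2, 4): 0.09,
    (3, 4): 0.05,
}

#: trait means the season effects are centered on (reduced scale)
_TRAIT_MEANS = np.array([10.06, 262.30, 53.32, 13.58, 29.98])


def model_c_g0() -> np.ndarray:
    sd = np.sqrt(_MODEL_C_GVAR)
    corr = np.eye(5)
    for (i, j), r in _MODEL_C_GCORR.items():
        corr[i, j] = corr[j, i] = r
    return corr * np.outer(sd, sd)


def _season_beta(lam: np.ndarray, psi: np.ndarray, n_seasons: int) -> np.ndarray:
    """Evenly spaced season effects, estimable but not dominant.

    Season s shifts trait j's reduced-scale mean by
    0.3 sqrt(psi_j) (s - (S-1)/2) around the trait mean; the structural-
    scale beta is the (I - Lambda)-image of those target means.
    """
    t = len(psi)
    offsets = 0.3 * np.sqrt(psi)[:, None] * (
        np.arange(n_seasons)[None, :] - (n_seasons - 1) / 2.0
    )
    target = _TRAIT_MEANS[:t, None] + offsets
    return (np.eye(t) - lam) @ target


def scenario_presets(name: str, seed: int = 20110037) -> SimulationScenario:
    """Named generating models.

    - ``paper_model_C``: 5 traits, 6 seasons, causal graph BW->AEW and
      W35->AFE->NE with the reported posterior-mean coefficients and
      dispersion values; 840 phenotyped hens (the most recent cohorts) on
      a 1350-animal pedigree whose earlier cohorts are unphenotyped
      ancestors.  The breeding design keeps sixty families per generation
      so that relatedness varies across the flock — the contrast the
      model needs to separate genetic from residual (co)variances.
    - ``null_no_causal``: same dispersion scale, Lambda = 0.
    - ``fully_recursive_demo``: all 10 lower-triangular entries free, with
      modest standardized coefficients.
    """
    known = ("paper_model_C", "null_no_causal", "fully_recursive_demo")
    if name not in known:
        raise ScenarioError(f"unknown preset {name!r}; choose one of {known}")
    plan = PedigreePlan()
    g0 = model_c_g0()
    psi = _MODEL_C_PSI.copy()
    n_phenotyped = 840  # hens with records, close to the 849 of the study
    if name == "paper_model_C":
        structure = CausalStructure(
            traits=TRAITS,
            edges=frozenset((p, c) for p, c, _ in _MODEL_C_LAMBDA),
        )
        lam_values = _MODEL_C_LAMBDA
    elif name == "null_no_causal":
        structure = CausalStructure.empty(TRAITS)
        lam_values = ()
    else:
        structure = CausalStructure.fully_recursive(TRAITS)
        # standardized coefficient 0.25, alternating sign, on the raw scale
        lam_values = tuple(
            (
                TRAITS[j],
                TRAITS[i],
                (0.25 if (i + j) % 2 == 0 else -0.25)
                * np.sqrt(psi[i] / psi[j]),
            )
            for i in range(5)
            for j in range(i)
        )
    lam = structure.lambda_from_edge_values({(p, c): v for p, c, v in lam_values})
    beta = _season_beta(lam, psi, 6)
    return SimulationScenario(
        plan=plan,
        structure=structure,
        lambda_values=lam_values,
        g0=g0,
        psi=psi,
        beta=beta,
        n_phenotyped=n_phenotyped,
        n_seasons=6,
        seed=seed,
    )


def shrink_scenario(
    scenario: SimulationScenario,
    *,
    n_founders: int,
    n_generations: int,
    n_matings: int,
    n_offspring: int,
    seed: int | None = None,
) -> SimulationScenario:
    """Same generating model on a smaller breeding design (for test scale).

    Resets ``n_phenotyped`` to "all non-founders": a preset's absolute
    count would otherwise spill onto founders of a smaller design.
    """
    return replace(
        scenario,
        plan=PedigreePlan(n_founders, n_generations, n_matings, n_offspring),
        n_phenotyped=0,
        seed=scenario.seed if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# file output

def write_dataset(dataset: Dataset, phen_path, ped_path, truth_path=None) -> None:
    """Phenotype CSV + pedigree CSV (+ JSON truth sidecar)."""
    df = dataset.phenotypes.copy()
    df.columns = ["animal", "season"] + [t.lower() for t in dataset.traits]
    df.to_csv(phen_path, index=False)
    write_pedigree(dataset.pedigree, ped_path)
    if truth_path is not None:
        sc = dataset.truth["scenario"]
        payload = {
            "traits": list(sc.traits),
            "edges": sorted(list(e) for e in sc.structure.edges),
            "lambda_values": [list(v) for v in sc.lambda_values],
            "g0": sc.g0.tolist(),
            "psi": sc.psi.tolist(),
            "beta": sc.beta.tolist(),
            "n_seasons": sc.n_seasons,
            "seed": sc.seed,
            "u": dataset.truth["u"].tolist(),
            "e": dataset.truth["e"].tolist(),
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh)
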