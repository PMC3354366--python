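import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import phenonet as pn

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def random_pedigree_records(rng: np.random.Generator, n: int):
    """Random valid pedigree: each animal's parents drawn among earlier
    animals (or unknown), so topological validity holds by construction."""
    records = []
    for i in range(n):
        if i < 2 or rng.random() < 0.25:
            records.append((f"a{i}", None, None))
        else:
            s = f"a{rng.integers(i)}"
            d = f"a{rng.integers(i)}"
            if s == d:
                d = None
            records.append((f"a{i}", s, d))
    return records


@pytest.fixture(scope="session")
def trio_pedigree():
    return pn.validate_and_sort([("s", 0, 0), ("d", 0, 0), ("o", "s", "d")])


@pytest.fixture(scope="session")
def small_scenario():
    """Shrunk quail scenario: same generating model, desk-scale pedigree."""
    sc = pn.scenario_presets("paper_model_C", seed=42)
    return pn.shrink_scenario(
        sc, n_founders=30, n_generations=3, n_matings=15, n_offspring=5
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return pn.simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_chain(small_dataset, small_scenario):
    """True-structure fit on the small dataset (shared: fits are costly)."""
    return pn.fit_sem(
        small_dataset,
        small_scenario.structure,
        settings=pn.McmcSettings(iterations=1200, burn_in=400, thin=1, seed=9),
    )


@pytest.fixture(scope="session")
def replicate_study():
    """Twenty replicates of the quail scenario at study scale: fully
    recursive (MTAM) fit, 95%-content IC search, true-structure refit and
    DIC for both.  Several tests assert different claims on this shared
    computation (it dominates the suite's runtime)."""
    from phenonet.compare import dic

    out = []
    for rep in range(20):
        sc = pn.scenario_presets("paper_model_C", seed=7000 + rep)
        ds = pn.simulate_dataset(sc)
        mtam = pn.fit_fully_recursive(
            ds, settings=pn.McmcSettings(4000, 1500, 1, 7100 + rep)
        )
        chain_true = pn.fit_sem(
            ds,
            sc.structure,
            settings=pn.McmcSettings(4000, 1500, 1, 7200 + rep),
        )
        res = pn.search_over_contents(mtam.r0_star, pn.TRAITS, (0.95,))
        dic_true = dic(chain_true, ds, "true")
        dic_mtam = dic(mtam, ds, "MTAM")
        out.append(
            {
                "skeleton": frozenset(res.graphs[0.95].skeleton_edges()),
                "dic_true": dic_true.dic,
                "dic_mtam": dic_mtam.dic,
                "dbar_true": dic_true.dbar,
                "dbar_mtam": dic_mtam.dbar,
            }
        )
    return out


@pytest.fixture(scope="session")
def small_fr_chain(small_dataset):
    """Fully recursive (MTAM) fit on the small dataset."""
    return pn.fit_fully_recursive(
        small_dataset,
        settings=pn.McmcSettings(iterations=1200, burn_in=400, thin=1, seed=10),
    )
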