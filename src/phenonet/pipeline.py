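"""End-to-end study workflow: fit, search, orient, compare, report.

The three-stage procedure: (1) fit a fully recursive SEM — likelihood-
equivalent to the multiple-trait animal model — to obtain posterior draws
of the genetic-effects-conditional residual covariance R0*; (2) run the IC
algorithm on those draws at one or more HPD contents, then orient
remaining undirected edges from temporal knowledge; (3) refit an SEM under
each distinct selected structure and compare against the MTAM by DIC,
reporting reduced-scale dispersion summaries for the preferred model.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import ComparisonReport, compare as compare_dic, dataset_key, dic
from .gibbs import (
    Hyperparameters,
    McmcSettings,
    PosteriorChain,
    fit_fully_recursive,
    fit_sem,
    posterior_summary,
)
from .pedigree import Pedigree, read_pedigree
from .search import PartialGraph, SearchResult, search_over_contents, temporal_orient
from .sem import CausalStructure
from .simulate import TRAITS, Dataset, scenario_presets, simulate_dataset

logger = logging.getLogger("phenonet")

#: temporal ranks of the quail traits: BW hatches first, W35 next, AFE
#: next, egg weight and egg number are expressed over the same window
DEFAULT_TIME_ORDER: dict[str, int] = {"BW": 0, "W35": 1, "AFE": 2, "AEW": 3, "NE": 3}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the quail analysis."""

    preset: str | None = "paper_model_C"
    phenotype_path: str | None = None
    pedigree_path: str | None = None
    traits: tuple[str, ...] = TRAITS
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    settings: McmcSettings = field(default_factory=McmcSettings)
    contents: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
    time_order: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TIME_ORDER)
    )
    outdir: str = "phenonet_run"
    seed: int = 1

    def __post_init__(self):
        for c in self.contents:
            if not 0.0 < c < 1.0:
                raise PipelineError(f"HPD content {c} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("preset", "phenotype_path", "pedigree_path", "outdir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "traits" in raw:
            kwargs["traits"] = tuple(raw["traits"])
        if "contents" in raw:
            kwargs["contents"] = tuple(float(c) for c in raw["contents"])
        if "time_order" in raw:
            kwargs["time_order"] = {str(k): int(v) for k, v in raw["time_order"].items()}
        if "mcmc" in raw:
            kwargs["settings"] = McmcSettings(**raw["mcmc"])
        if "hyperparameters" in raw:
            h = raw["hyperparameters"]
            kwargs["hyper"] = Hyperparameters(
                nu_g=float(h.get("nu_g", 7.0)),
                g0_scale=np.asarray(h["g0_scale"], dtype=float)
                if "g0_scale" in h
                else Hyperparameters().g0_scale,
                nu_psi=float(h.get("nu_psi", 3.0)),
                s2=np.asarray(h["s2"], dtype=float)
                if "s2" in h
                else Hyperparameters().s2,
            )
        return cls(**kwargs)

    def to_yaml(self) -> str:
        payload = {
            "preset": self.preset,
            "phenotype_path": self.phenotype_path,
            "pedigree_path": self.pedigree_path,
            "traits": list(self.traits),
            "contents": list(self.contents),
            "time_order": self.time_order,
            "mcmc": dataclasses.asdict(self.settings),
            "hyperparameters": {
                "nu_g": self.hyper.nu_g,
                "g0_scale": np.asarray(self.hyper.g0_scale).tolist(),
                "nu_psi": self.hyper.nu_psi,
                "s2": np.asarray(self.hyper.s2).tolist(),
            },
            "outdir": self.outdir,
            "seed": self.seed,
        }
        return yaml.safe_dump(payload, sort_keys=False)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: PipelineConfig
    dataset_key: str
    search: SearchResult
    oriented: dict[float, PartialGraph]
    structures: dict[str, CausalStructure]
    chains: dict[str, PosteriorChain]
    dic_table: ComparisonReport
    preferred: str
    summaries: dict[str, dict]
    warnings: list[str]


# ---------------------------------------------------------------------------
# input handling

def read_phenotypes(path, traits: tuple[str, ...], pedigree: Pedigree) -> Dataset:
    """Read a delimited phenotype table (animal, season, one col per trait).

    Missing values are rejected (with the offending row and column named);
    season codes are mapped to contiguous 0-based indices; every animal
    must appear in the pedigree.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    need = ["animal", "season"] + [t.lower() for t in traits]
    for col in need:
        if col not in lower:
            raise PipelineError(f"phenotype file lacks column {col!r}")
    out = df[[lower[c] for c in need]].copy()
    out.columns = ["animal", "season"] + list(traits)
    for col in out.columns:
        mask = out[col].isna()
        if mask.any():
            row = int(np.where(mask)[0][0])
            raise PipelineError(
                f"missing value at row {row + 2}, column {col!r}"
            )
    out["animal"] = out["animal"].astype(str)
    known = set(pedigree.ids)
    unknown = [a for a in out["animal"] if a not in known]
    if unknown:
        raise PipelineError(
            f"phenotyped animal(s) absent from pedigree: {unknown[:5]}"
        )
    codes = sorted(out["season"].unique())
    out["season"] = out["season"].map({c: i for i, c in enumerate(codes)})
    out[list(traits)] = out[list(traits)].astype(float)
    return Dataset(phenotypes=out, pedigree=pedigree, traits=tuple(traits))


def _load_dataset(config: PipelineConfig) -> Dataset:
    if config.preset:
        scenario = scenario_presets(config.preset, seed=config.seed)
        return simulate_dataset(scenario)
    if not (config.phenotype_path and config.pedigree_path):
        raise PipelineError("config needs either a preset or both input paths")
    ped = read_pedigree(config.pedigree_path)
    return read_phenotypes(config.phenotype_path, config.traits, ped)


# ---------------------------------------------------------------------------
# the pipeline

def _graph_to_structure(graph: PartialGraph) -> CausalStructure | None:
    """A fully directed, conflict-free graph becomes a causal structure."""
    if graph.undirected or graph.conflicts:
        return None
    return CausalStructure(traits=graph.nodes, edges=frozenset(graph.directed))


def _structure_name(structure: CausalStructure) -> str:
    if not structure.edges:
        return "empty"
    return "+".join(f"{p}>{c}" for p, c in sorted(structure.edges))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow; deterministic given the config seed."""
    warnings: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("data")
        dataset = _load_dataset(config)
    except Exception as exc:
        raise PipelineError(f"[data] {exc}") from exc

    try:
        stage("fit fully recursive (MTAM)")
        mtam_chain = fit_fully_recursive(
            dataset, config.hyper, dataclasses.replace(config.settings, seed=config.seed)
        )
    except Exception as exc:
        raise PipelineError(f"[mtam-fit] {exc}") from exc

    try:
        stage("causal search")
        search = search_over_contents(
            mtam_chain.r0_star, tuple(dataset.traits), config.contents
        )
        skipped = sum(r.n_skipped for r in search.decision_function.log)
        if skipped:
            warnings.append(f"{skipped} singular draws skipped across queries")
        oriented: dict[float, PartialGraph] = {}
        for c, g in search.graphs.items():
            oriented[c] = temporal_orient(g, config.time_order)
    except Exception as exc:
        raise PipelineError(f"[search] {exc}") from exc

    try:
        stage("refit selected structures")
        structures: dict[str, CausalStructure] = {}
        for c, g in oriented.items():
            s = _graph_to_structure(g)
            if s is None:
                warnings.append(
                    f"HPD {c:.0%}: graph not fully oriented "
                    f"(undirected: {sorted(g.undirected)}, conflicts: "
                    f"{g.conflicts}); SEM fit skipped"
                )
                continue
            structures[_structure_name(s)] = s
        chains: dict[str, PosteriorChain] = {"MTAM": mtam_chain}
        for k, (name, s) in enumerate(sorted(structures.items())):
            chains[name] = fit_sem(
                dataset,
                s,
                config.hyper,
                dataclasses.replace(config.settings, seed=config.seed + 1 + k),
            )
    except Exception as exc:
        raise PipelineError(f"[refit] {exc}") from exc

    try:
        stage("model comparison")
        results = [dic(ch, dataset, model=name) for name, ch in chains.items()]
        table = compare_dic(results)
        preferred = table.best().model
    except Exception as exc:
        raise PipelineError(f"[dic] {exc}") from exc

    try:
        stage("summaries")
        summaries = {
            name: _chain_summary(ch) for name, ch in chains.items()
        }
    except Exception as exc:
        raise PipelineError(f"[summaries] {exc}") from exc

    return RunReport(
        config=config,
        dataset_key=dataset_key(dataset),
        search=search,
        oriented=oriented,
        structures=structures,
        chains=chains,
        dic_table=table,
        preferred=preferred,
        summaries=summaries,
        warnings=warnings,
    )


def _chain_summary(chain: PosteriorChain) -> dict:
    """Structural coefficients, dispersion and reduced-scale summaries."""
    traits = chain.traits
    out: dict = {"lambda": {}, "psi": {}, "h2": {}, "r0_star": {}, "g0": {}}
    for p, c in sorted(chain.structure.edges):
        s = posterior_summary(chain, f"lambda:{p}->{c}")
        out["lambda"][f"{p}->{c}"] = dataclasses.asdict(s)
    for t in traits:
        out["psi"][t] = dataclasses.asdict(posterior_summary(chain, f"psi:{t}"))
        out["h2"][t] = dataclasses.asdict(posterior_summary(chain, f"h2:{t}"))
    for i, a in enumerate(traits):
        for b in traits[i:]:
            out["r0_star"][f"{a},{b}"] = dataclasses.asdict(
                posterior_summary(chain, f"r0_star:{a},{b}")
            )
            out["g0"][f"{a},{b}"] = dataclasses.asdict(
                posterior_summary(chain, f"g0:{a},{b}")
            )
    return out


# ---------------------------------------------------------------------------
# report files

def write_report(report: RunReport, outdir) -> list[Path]:
    """Write graphs (DOT, GraphML, edge list), tables (CSV), decision log,
    JSON summary and a config echo; returns the paths written."""
    import networkx as nx

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        written.append(p)

    for c, g in report.oriented.items():
        tag = f"hpd{int(round(c * 100))}"
        emit(f"graph_{tag}.dot", g.to_dot())
        emit(f"graph_{tag}.edgelist", g.to_edge_list())
        p = out / f"graph_{tag}.graphml"
        nx.write_graphml(g.to_networkx(), p)
        written.append(p)

    rows = []
    for rec in report.search.decision_function.log:
        rows.append(
            {
                "trait_1": rec.pair[0],
                "trait_2": rec.pair[1],
                "conditioning": "|".join(rec.conditioning),
                "mean": rec.mean,
                "hpd_lower": rec.hpd_lower,
                "hpd_upper": rec.hpd_upper,
                "content": rec.content,
                "verdict": "null" if rec.null else "dependent",
                "n_skipped": rec.n_skipped,
            }
        )
    p = out / "decision_log.csv"
    with open(p, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["empty"])
        w.writeheader()
        w.writerows(rows)
    written.append(p)

    p = out / "dic.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "DIC", "Dbar", "D_at_mean", "pD", "delta"])
        for res, d in zip(report.dic_table.ranked, report.dic_table.deltas):
            w.writerow([res.model, res.dic, res.dbar, res.d_at_mean, res.p_d, d])
    written.append(p)

    emit("dic.txt", report.dic_table.to_text() + "\n")
    config_text = report.config.to_yaml()
    emit("config.yaml", config_text)
    summary = {
        "dataset": report.dataset_key,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": report.config.seed,
        "preferred_model": report.preferred,
        "stable_edges": sorted(list(e) for e in report.search.stable_edges),
        "warnings": report.warnings,
        "summaries": report.summaries,
    }
    emit("summary.json", json.dumps(summary, indent=1, default=float))
    emit("stability.txt", report.search.stability_report() + "\n")
    return written
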