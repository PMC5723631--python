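"""End-to-end orchestration of the syndrome-evolution analysis.

Stages, in dependency order: species reconciliation -> coverage filter ->
nearest-neighbour imputation -> per-syndrome rank-correlation PCA ->
two-group discretization -> per-syndrome Mk ancestral reconstruction ->
Pagel correlated-evolution tests on all syndrome pairs -> pPCA of the four
syndrome scores -> three-way strategy assignment and 3-state Mk fit ->
(optional) phylogenetic ANOVA against tropical affinity and MPD
representativeness null test. Every stochastic stage takes an explicit seed;
rerunning the same configuration reproduces the report bit-for-bit (apart
from the timestamp).
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .markov import (MkModel, PagelModel, profile_rate_intervals)
from .phylometrics import PhyloANOVA, PhyloPCA, mpd_null_test
from .syndromes import (SyndromeDefinition, SpearmanPCA, assign_strategies,
                        load_syndrome_definitions, split_two_groups)
from .traits import TraitMatrix, filter_low_coverage, impute_nearest_neighbor, read_tropical_affinity
from .tree import Phylogeny

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_analysis",
           "summarize_transitions", "StageError"]

logger = logging.getLogger("syndromevo")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """File-based configuration for :func:`run_pipeline`."""

    tree: str
    traits: str
    syndromes: str
    affinity: str | None = None
    pool_tree: str | None = None
    trait_metadata: str | None = None
    outdir: str | None = None
    seed: int = 0
    min_coverage: float = 0.5
    n_perm: int = 999
    n_sim: int = 1000
    mpd_reps: int = 1000
    root_prior: str = "uniform"
    mk_restarts: int = 10
    pagel_restarts: int = 3
    kmeans_restarts: int = 100
    standardize_ppc: bool = False
    max_species_mismatch: float = 0.5
    profile_intervals: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for attr in ("tree", "traits", "syndromes", "affinity", "pool_tree",
                     "trait_metadata"):
            p = getattr(cfg, attr)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"config {attr}: no such file {p!r}")
        return cfg


@dataclass
class RunReport:
    """All stage outputs of one pipeline run, JSON-serializable."""

    syndromes: dict
    mk_fits: dict
    pagel: list
    ppca: dict
    strategies: dict
    strategy_fit: dict
    anova: dict
    mpd: dict | None
    transitions: list
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "syndromes": self.syndromes,
            "mk_fits": self.mk_fits,
            "pagel": self.pagel,
            "ppca": self.ppca,
            "strategies": self.strategies,
            "strategy_fit": self.strategy_fit,
            "anova": self.anova,
            "mpd": self.mpd,
            "transitions": self.transitions,
            "provenance": self.provenance,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                logger.info("stage %s", name)
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _syndrome_payload(res, states) -> dict:
    return {
        "scores": {s: float(v) for s, v in res.scores.items()},
        "loadings": {v: float(l) for v, l in res.loadings.items()},
        "eigenvalues": [float(e) for e in res.eigenvalues],
        "variance_fraction_pc1": res.variance_fraction_pc1,
        "states": {s: str(v) for s, v in states.items()},
    }


def run_analysis(matrix: TraitMatrix, tree: Phylogeny,
                 definitions: list[SyndromeDefinition],
                 affinity: pd.Series | None = None,
                 pool_tree: Phylogeny | None = None,
                 config: PipelineConfig | None = None) -> RunReport:
    """Run all stages on in-memory inputs (the library-level entry point)."""
    cfg = config or PipelineConfig(tree="", traits="", syndromes="")
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(2 ** 31)) for name in
             ("pagel", "kmeans", "anova", "mpd", "mk")}

    # --- reconcile species sets -------------------------------------
    tree_sp = set(tree.tip_labels)
    trait_sp = set(matrix.species)
    shared = [s for s in matrix.species if s in tree_sp]
    dropped = sorted((tree_sp | trait_sp) - set(shared))
    union = len(tree_sp | trait_sp)
    if union and len(dropped) / union > cfg.max_species_mismatch:
        raise StageError(
            f"stage 'reconcile' failed: {len(dropped)}/{union} species not "
            "shared between tree and traits"
        )
    if dropped:
        logger.warning("dropping %d species absent from tree or traits: %s",
                       len(dropped), dropped)
    matrix = matrix.subset_species(shared)

    # --- coverage filter + imputation -------------------------------
    @_stage("filter")
    def do_filter():
        return filter_low_coverage(matrix, cfg.min_coverage)

    kept, excluded = do_filter()

    @_stage("impute")
    def do_impute():
        return impute_nearest_neighbor(kept)

    complete = do_impute()
    table = complete.to_frame()

    # --- syndrome construction --------------------------------------
    @_stage("syndromes")
    def do_syndromes():
        out = {}
        for d in definitions:
            cols = [v for v in d.variables if v in table.columns]
            if len(cols) < 2:
                raise ValueError(f"syndrome {d.name} has <2 available variables")
            res = SpearmanPCA(table[cols], d).fit()
            res.states = split_two_groups(res.scores)
            out[d.name] = res
        return out

    syn = do_syndromes()
    names = list(syn)
    scores = pd.DataFrame({n: syn[n].scores for n in names})
    states = pd.DataFrame({n: syn[n].states for n in names})

    # --- ancestral states per syndrome ------------------------------
    @_stage("ancestral")
    def do_ancestral():
        fits = {}
        for n in names:
            m = MkModel(tree, states[n], states=("A", "B"),
                        root_prior=cfg.root_prior)
            fits[n] = (m, m.fit(restarts=cfg.mk_restarts, seed=seeds["mk"]))
        return fits

    mk_fits = do_ancestral()

    # --- Pagel pairwise tests ----------------------------------------
    @_stage("pagel")
    def do_pagel():
        out = []
        for a, b in itertools.combinations(names, 2):
            res = PagelModel(tree, states[a], states[b],
                             root_prior=cfg.root_prior).fit(
                restarts=cfg.pagel_restarts, seed=seeds["pagel"])
            d = res.to_dict()
            d["pair"] = [a, b]
            out.append(d)
        return out

    pagel = do_pagel()

    # --- pPCA + strategies -------------------------------------------
    @_stage("ppca")
    def do_ppca():
        return PhyloPCA(scores, tree).fit()

    ppca_res = do_ppca()

    @_stage("strategies")
    def do_strategies():
        anc = (states == "A").all(axis=1)
        sex = scores.get("sexual_dimorphism")
        assignment = assign_strategies(
            ppca_res.species_scores.iloc[:, :3], ancestral_mask=anc,
            sex_scores=sex, restarts=cfg.kmeans_restarts,
            seed=seeds["kmeans"], standardize=cfg.standardize_ppc,
        )
        model = MkModel(tree, assignment.labels, states=("A", "B1", "B2"),
                        root_prior=cfg.root_prior)
        fit = model.fit(restarts=cfg.mk_restarts, seed=seeds["mk"])
        return assignment, model, fit

    assignment, strat_model, strat_fit = do_strategies()

    # --- phylogenetic ANOVA -------------------------------------------
    anova = {}
    if affinity is not None:
        @_stage("anova")
        def do_anova():
            out = {}
            grp = affinity.map(lambda b: "tropical" if b else "nontropical")
            for n in names:
                res = PhyloANOVA(scores[n], grp, tree).fit(
                    n_sim=cfg.n_sim, seed=seeds["anova"])
                out[n] = {
                    "f_statistic": res.f_statistic,
                    "p_simulated": res.p_simulated,
                    "n_simulations": res.n_simulations,
                    "bm_rate": res.bm_rate,
                    "group_means": {k: float(v)
                                    for k, v in res.group_means.items()},
                }
            return out

        anova = do_anova()

    # --- MPD representativeness ---------------------------------------
    mpd_payload = None
    if pool_tree is not None:
        @_stage("mpd")
        def do_mpd():
            focal = [s for s in complete.species
                     if s in set(pool_tree.tip_labels)]
            res = mpd_null_test(pool_tree, focal, reps=cfg.mpd_reps,
                                seed=seeds["mpd"])
            return {"observed": res.observed, "p_quantile": res.p_quantile,
                    "reps": len(res.null_distribution)}

        mpd_payload = do_mpd()

    # --- transition summary -------------------------------------------
    transitions = summarize_transitions(
        {n: mk_fits[n] for n in names}, (strat_model, strat_fit),
        profile=cfg.profile_intervals,
    )

    report = RunReport(
        syndromes={n: _syndrome_payload(syn[n], states[n]) for n in names},
        mk_fits={n: mk_fits[n][1].to_dict() for n in names},
        pagel=pagel,
        ppca={
            "eigenvalues": [float(e) for e in ppca_res.eigenvalues],
            "axis_loadings": {
                c: {v: float(x) for v, x in ppca_res.axis_loadings[c].items()}
                for c in ppca_res.axis_loadings.columns
            },
            "species_scores": {
                c: {s: float(x) for s, x in ppca_res.species_scores[c].items()}
                for c in ppca_res.species_scores.columns[:3]
            },
        },
        strategies={
            "labels": {s: str(v) for s, v in assignment.labels.items()},
            "counts": {k: int(v) for k, v in assignment.counts().items()},
            "inertia": assignment.inertia,
        },
        strategy_fit=strat_fit.to_dict(),
        anova=anova,
        mpd=mpd_payload,
        transitions=transitions,
        provenance={
            "package": "syndromevo",
            "version": __version__,
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "excluded_low_coverage": excluded,
            "dropped_unmatched": dropped,
            "n_species": complete.n_species,
            "n_traits": complete.n_traits,
        },
    )
    return report


def summarize_transitions(mk_fits: dict, strategy_fit=None,
                          profile: bool = False) -> list[dict]:
    """Tabulate every fitted transition rate (one row per free or fixed rate)
    with optional profile-likelihood 95% intervals."""
    rows = []

    def add(character, model, results):
        k = len(results.model.states)
        intervals = None
        if profile:
            intervals = profile_rate_intervals(model, results)
            intervals = {(r["from"], r["to"]): (r["ci_low"], r["ci_high"])
                         for _, r in intervals.iterrows()}
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                frm, to = str(results.model.states[i]), str(results.model.states[j])
                free = bool(results.model.constraint_mask[i, j])
                row = {
                    "character": character,
                    "from": frm,
                    "to": to,
                    "rate": float(results.model.rates[i, j]),
                    "free": free,
                }
                if intervals is not None and free:
                    row["ci_low"], row["ci_high"] = intervals[(frm, to)]
                rows.append(row)

    for name, (model, results) in mk_fits.items():
        add(name, model, results)
    if strategy_fit is not None:
        add("strategy", strategy_fit[0], strategy_fit[1])
    return rows


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis from files named in the config; writes
    report.json plus per-stage CSVs when an output directory is set."""
    tree = Phylogeny.read(config.tree)
    matrix = TraitMatrix.read_csv(config.traits, config.trait_metadata)
    definitions = load_syndrome_definitions(config.syndromes)
    affinity = (read_tropical_affinity(config.affinity)
                if config.affinity else None)
    pool = Phylogeny.read(config.pool_tree) if config.pool_tree else None
    report = run_analysis(matrix, tree, definitions, affinity=affinity,
                          pool_tree=pool, config=config)
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        report.write(os.path.join(config.outdir, "report.json"))
        pd.DataFrame(report.transitions).to_csv(
            os.path.join(config.outdir, "transitions.csv"), index=False)
        pd.DataFrame({n: pd.Series(s["scores"])
                      for n, s in report.syndromes.items()}).to_csv(
            os.path.join(config.outdir, "syndrome_scores.csv"),
            index_label="species")
        pd.Series(report.strategies["labels"]).rename("strategy").to_csv(
            os.path.join(config.outdir, "strategies.csv"),
            index_label="species")
    return report
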