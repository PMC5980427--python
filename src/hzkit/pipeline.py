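"""End-to-end orchestration of the hybrid-zone analysis on synthetic or
user-supplied data.

Stages: simulate (or load) genotypes -> diversity and pairwise
differentiation -> linkage-disequilibrium region scans -> Mantel isolation
by distance -> supervised admixture of the study panel and of a simulated
cross panel -> hybrid-class binning and assignment -> niche identity and
background similarity tests on a synthetic landscape.  Each stage writes
CSV artifacts plus a JSON manifest of seeds and configuration; reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .admixture import AdmixtureConfig, fit_admixture
from .cross_simulator import build_cross_panel
from .hybrid_classification import (
    DEFAULT_BINS,
    bin_q_values,
    classify_by_class_ranges,
    conservative_groups,
    derive_class_ranges,
)
from .niche import NicheModelConfig, background_similarity_test, identity_test
from .popgen_stats import (
    LDChainParams,
    diversity_summary,
    mantel_ibd,
    pairwise_dest,
    pairwise_fst,
    region_ld_scan,
)
from .synthetic_data import (
    NicheScenario,
    default_study_fixture,
    make_landscape,
    make_occurrence_scenario,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline run."""

    out_dir: str = "hzkit_run"
    seed: int = 1
    # stage toggles
    run_popgen: bool = True
    run_ld: bool = True
    run_mantel: bool = True
    run_admixture: bool = True
    run_crosses: bool = True
    run_classification: bool = True
    run_niche: bool = True
    # inputs; None means simulate
    genotypes_path: str | None = None
    metadata_path: str | None = None
    # stage settings
    n_bootstrap: int = 1000
    ld_chain: LDChainParams = field(default_factory=LDChainParams)
    mantel_permutations: int = 9999
    mantel_drop: list[str] = field(default_factory=lambda: ["Menorca"])
    admixture: AdmixtureConfig = field(default_factory=AdmixtureConfig)
    per_class_n: int = 50
    niche: NicheModelConfig = field(default_factory=NicheModelConfig)
    niche_reps: int = 100
    niche_scenario: str = "displaced"
    landscape_shape: tuple[int, int] = (120, 160)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("ld_chain", LDChainParams),
            ("admixture", AdmixtureConfig),
            ("niche", NicheModelConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "landscape_shape" in raw:
            raw["landscape_shape"] = tuple(raw["landscape_shape"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(ctx, *a, **k):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(ctx, *a, **k)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            ctx["timings"][name] = round(dt, 3)
            logger.info("stage %s: done in %.1fs", name, dt)
            return out

        return wrapped

    return deco


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dictionary."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in (
            "fixture",
            "bootstrap",
            "ld",
            "mantel",
            "admixture",
            "crosses",
            "cross_admixture",
            "landscape",
            "occurrences",
            "niche",
        )
    }
    ctx: dict = {"timings": {}, "artifacts": []}

    # ---- data ------------------------------------------------------------
    if cfg.genotypes_path:
        panel = iof.read_structure_matrix(cfg.genotypes_path)
        metadata = (
            iof.read_population_metadata(cfg.metadata_path)
            if cfg.metadata_path
            else []
        )
        if metadata:
            sp = {m.population: m.species_label for m in metadata}
            panel.species_label = [
                sp.get(p, s) for p, s in zip(panel.population, panel.species_label)
            ]
    else:
        panel, metadata = default_study_fixture(seed=seeds["fixture"])
        iof.write_structure_matrix(panel, str(out / "genotypes.str"))
        iof.write_genepop(panel, str(out / "genotypes.gen"))
        iof.write_population_metadata(metadata, str(out / "metadata.csv"))
        ctx["artifacts"] += ["genotypes.str", "genotypes.gen", "metadata.csv"]

    eco = {m.population: m.ecology for m in metadata}
    sp_of = {m.population: m.species_label for m in metadata}

    def _emit(df: pd.DataFrame, name: str, index=True):
        df.to_csv(out / name, index=index)
        ctx["artifacts"].append(name)

    # ---- popgen ----------------------------------------------------------
    if cfg.run_popgen:
        @_stage("diversity")
        def _div(ctx):
            _emit(diversity_summary(panel), "diversity.csv")

        _div(ctx)

        @_stage("differentiation")
        def _diff(ctx):
            for stat, fn in (("fst", pairwise_fst), ("dest", pairwise_dest)):
                mat = fn(panel, n_bootstrap=cfg.n_bootstrap, seed=seeds["bootstrap"])
                _emit(mat.to_frame(), f"{stat}.csv")
                ci = pd.DataFrame(
                    mat.ci_low, index=mat.populations, columns=mat.populations
                )
                _emit(ci, f"{stat}_ci_low.csv")
                _emit(
                    pd.DataFrame(
                        mat.ci_high, index=mat.populations, columns=mat.populations
                    ),
                    f"{stat}_ci_high.csv",
                )
                ctx.setdefault("matrices", {})[stat] = mat

        _diff(ctx)

    if cfg.run_ld:
        @_stage("ld_scan")
        def _ld(ctx):
            regions = {
                "elegans_allopatric": [
                    p
                    for p in panel.populations
                    if sp_of.get(p) == "Ie" and eco.get(p) != "sympatric_introgressed"
                ],
                "sympatric": [
                    p
                    for p in panel.populations
                    if eco.get(p) == "sympatric_introgressed"
                ],
                "graellsii_allopatric": [
                    p for p in panel.populations if sp_of.get(p) == "Ig"
                ],
            }
            rows = []
            for name, pops in regions.items():
                if not pops:
                    continue
                _, summary = region_ld_scan(
                    panel, pops, cfg.ld_chain, seed=seeds["ld"]
                )
                summary.insert(0, "region", name)
                rows.append(summary)
            _emit(pd.concat(rows, ignore_index=True), "ld_summary.csv", index=False)

        _ld(ctx)

    if cfg.run_mantel and cfg.run_popgen and metadata:
        @_stage("mantel")
        def _mantel(ctx):
            mat = ctx["matrices"]["fst"]
            rows = []
            for label, drop in (("all", None), ("drop_outliers", cfg.mantel_drop)):
                try:
                    res = mantel_ibd(
                        mat,
                        metadata,
                        n_permutations=cfg.mantel_permutations,
                        seed=seeds["mantel"],
                        drop=drop,
                    )
                except ValueError as exc:
                    logger.warning("mantel (%s) skipped: %s", label, exc)
                    continue
                rows.append(
                    {
                        "analysis": label,
                        "r": res.r,
                        "p": res.p,
                        "n_permutations": res.n_permutations,
                        "n_populations": len(res.populations),
                    }
                )
            _emit(pd.DataFrame(rows), "mantel.csv", index=False)

        _mantel(ctx)

    # ---- admixture -------------------------------------------------------
    if cfg.run_admixture:
        @_stage("admixture")
        def _admix(ctx):
            acfg = AdmixtureConfig(**{**asdict(cfg.admixture), "seed": seeds["admixture"]})
            res = fit_admixture(panel, acfg)
            ctx["admixture_result"] = res
            _emit(res.to_frame(), "admixture_individuals.csv", index=False)

        _admix(ctx)

    if cfg.run_crosses:
        @_stage("crosses")
        def _crosses(ctx):
            cross = build_cross_panel(
                panel, per_class_n=cfg.per_class_n, seed=seeds["crosses"]
            )
            ctx["cross_panel"] = cross
            acfg = AdmixtureConfig(
                **{**asdict(cfg.admixture), "seed": seeds["cross_admixture"]}
            )
            merged = type(panel).concatenate(
                [panel.subset(panel.reference_flag), cross.panel]
            )
            res = fit_admixture(merged, acfg)
            ctx["cross_admixture"] = res
            n_ref = int(panel.reference_flag.sum())
            ctx["cross_labels"] = ["reference"] * n_ref + cross.class_label
            df = res.to_frame()
            df["class"] = ctx["cross_labels"]
            _emit(df, "cross_admixture.csv", index=False)

        _crosses(ctx)

    if (
        cfg.run_classification
        and "admixture_result" in ctx
        and "cross_admixture" in ctx
    ):
        @_stage("classification")
        def _classify(ctx):
            res = ctx["admixture_result"]
            _emit(bin_q_values(res, DEFAULT_BINS), "assignment_bins.csv")
            cres = ctx["cross_admixture"]
            mask = [c != "reference" for c in ctx["cross_labels"]]
            sub_ids = np.flatnonzero(mask)
            import copy

            cross_only = copy.copy(cres)
            cross_only.individual_id = [cres.individual_id[i] for i in sub_ids]
            cross_only.population = [cres.population[i] for i in sub_ids]
            cross_only.q_mean = cres.q_mean[sub_ids]
            cross_only.q1_ci_low = cres.q1_ci_low[sub_ids]
            cross_only.q1_ci_high = cres.q1_ci_high[sub_ids]
            labels = [c for c in ctx["cross_labels"] if c != "reference"]
            _emit(bin_q_values(cross_only, DEFAULT_BINS), "cross_bins.csv")
            ranges = derive_class_ranges(cross_only, labels)
            _emit(ranges.table, "class_ranges.csv")
            groups = conservative_groups(ranges, preset="verbal")
            assign = classify_by_class_ranges(res, ranges, groups)
            _emit(assign, "class_assignments.csv", index=False)

        _classify(ctx)

    # ---- niche -----------------------------------------------------------
    if cfg.run_niche:
        @_stage("niche")
        def _niche(ctx):
            stack = make_landscape(*cfg.landscape_shape, seed=seeds["landscape"])
            for name in stack.variable_names:
                iof.write_ascii_grid(stack, name, str(out / f"{name}.asc"))
                ctx["artifacts"].append(f"{name}.asc")
            scenario = NicheScenario.preset(cfg.niche_scenario, stack)
            occ = make_occurrence_scenario(stack, scenario, seed=seeds["occurrences"])
            iof.write_occurrences(occ, str(out / "occurrences.csv"))
            ctx["artifacts"].append("occurrences.csv")
            names = list(occ)
            rows = []
            idr = identity_test(
                stack,
                occ[names[0]],
                occ[names[1]],
                cfg.niche,
                n_reps=cfg.niche_reps,
                seed=seeds["niche"],
            )
            rows.append(idr.to_row())
            for a, b in ((names[0], names[1]), (names[1], names[0])):
                bg = background_similarity_test(
                    stack,
                    occ[a],
                    occ[b],
                    config=cfg.niche,
                    n_reps=cfg.niche_reps,
                    seed=seeds["niche"],
                )
                rows.append(bg.to_row())
            _emit(pd.DataFrame(rows), "niche_summary.csv", index=False)

        _niche(ctx)

    manifest = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": _jsonable(asdict(cfg)),
        "artifacts": sorted(set(ctx["artifacts"])),
        "timings_s": ctx["timings"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
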