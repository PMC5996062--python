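"""End-to-end synthetic study orchestration.

One call reproduces the whole pipeline on a synthetic cohort: simulate ->
MAR-mask -> impute M datasets -> fit the four proportional-odds models ->
concordance evaluation -> fit the twelve cross-lagged pair models -> assemble
the significant-association graph.  Every artifact lands under one output
directory together with a manifest (seeds, stage status, file hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import apply_inclusion_filters, write_cohort
from .concordance import evaluate_fit
from .crosslag import VARPairSpec, assemble_graph, build_transition_frame, fit_bivariate_var, summarize_crosslag
from .diagnostics import MCMCConfig
from .missingness import ImputationModelSequence, MissingnessSpec, impute_sequential, mask_mar
from .propodds import ORTable, POModelSpec, fit_proportional_odds
from .scales import GH_SCALES, OH_INDICATORS
from .simulate import GeneratorConfig, TrueParams, simulate_cohort

log = logging.getLogger("ohga.study")

_SCENARIOS = {
    "default": TrueParams.default,
    "proportional_odds": TrueParams.for_proportional_odds,
    "crosslag": TrueParams.for_crosslag,
    "null": TrueParams.null,
}


@dataclass
class StudyConfig:
    """Configuration of one full synthetic study run."""

    seed: int = 0
    generator: GeneratorConfig = None
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    imputation: ImputationModelSequence = field(default_factory=ImputationModelSequence)
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(strict=False))
    po_options: dict = field(default_factory=dict)  # extra POModelSpec kwargs
    var_options: dict = field(default_factory=dict)  # extra VARPairSpec kwargs
    n_pred_draws: int = 200

    def __post_init__(self) -> None:
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        seed = int(d.get("seed", 0))
        gen_kwargs = dict(d.get("generator", {}))
        scenario = gen_kwargs.pop("scenario", d.get("scenario", "default"))
        tp = _SCENARIOS[scenario]()
        gen = GeneratorConfig(seed=gen_kwargs.pop("seed", seed), true_params=tp, **gen_kwargs)
        return cls(
            seed=seed,
            generator=gen,
            missingness=MissingnessSpec(**d.get("missingness", {})),
            imputation=ImputationModelSequence(**d.get("imputation", {})),
            mcmc=MCMCConfig(**{"strict": False, **d.get("mcmc", {})}),
            po_options=dict(d.get("po", {})),
            var_options=dict(d.get("var", {})),
            n_pred_draws=int(d.get("n_pred_draws", 200)),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full pipeline; returns (and writes) the artifact manifest.

    Any stage failure is recorded in the manifest with the stage name and the
    error; artifacts produced before the failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}, "failure": None}
    seed = int(config.seed)

    def record(stage: str, paths: dict) -> None:
        manifest["stages"].append(stage)
        for key, p in paths.items():
            manifest["artifacts"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
        log.info("stage %s done (%d artifacts)", stage, len(paths))

    def save_json(obj, path: Path) -> Path:
        path.write_text(json.dumps(obj, indent=2, default=float))
        return path

    t0 = time.time()
    try:
        cohort = simulate_cohort(config.generator)
        cohort, filter_report = apply_inclusion_filters(cohort)
        p = out / "synthetic.csv"
        write_cohort(cohort, p)
        record("simulate", {"synthetic": p, "filter_report": save_json(
            filter_report.to_dict(), out / "filter_report.json")})

        masked = mask_mar(cohort, config.missingness, seed=seed + 1)
        p = out / "masked.csv"
        write_cohort(masked, p)
        record("mask", {"masked": p})

        imputed = impute_sequential(masked, config.imputation, seed=seed + 2)
        paths = {}
        for m, comp in enumerate(imputed):
            pm = out / f"imputed_{m + 1}.csv"
            write_cohort(comp, pm)
            paths[f"imputed_{m + 1}"] = pm
        record("impute", paths)

        po_fits, paths = {}, {}
        for i, scale in enumerate(GH_SCALES):
            spec = POModelSpec(response=scale, mcmc=config.mcmc, **config.po_options)
            draws = fit_proportional_odds(imputed, spec, seed=seed + 10 + i)
            pm = out / f"po_{scale}.npz"
            draws.save(pm)
            paths[f"po_{scale}"] = pm
            if draws.diagnostics:
                paths[f"po_{scale}_diag"] = save_json(
                    [r.to_dict() for r in draws.diagnostics], out / f"po_{scale}_diag.json")
            po_fits[scale] = (spec, draws)
        table = ORTable.from_fits({s: d for s, (_, d) in po_fits.items()})
        paths["or_table"] = Path(table.to_csv(out / "or_table.csv"))
        record("fit_po", paths)

        paths = {}
        for i, scale in enumerate(GH_SCALES):
            spec, draws = po_fits[scale]
            ct, summ = evaluate_fit(draws, imputed[0], spec, seed=seed + 20 + i,
                                    n_draws=config.n_pred_draws)
            paths[f"eval_{scale}"] = save_json(summ.to_dict(), out / f"eval_{scale}.json")
            paths[f"contingency_{scale}"] = Path(ct.to_csv(out / f"contingency_{scale}.csv"))
        record("evaluate", paths)

        estimates, paths = {}, {}
        for i, gh in enumerate(GH_SCALES):
            for j, oh in enumerate(OH_INDICATORS):
                pair = VARPairSpec(gh=gh, oh=oh, mcmc=config.mcmc, **config.var_options)
                frames = [build_transition_frame(c, pair) for c in imputed]
                draws = fit_bivariate_var(frames, pair, seed=seed + 100 + 10 * i + j)
                pm = out / f"var_{gh}_{oh}.npz"
                draws.save(pm)
                paths[f"var_{gh}_{oh}"] = pm
                estimates[(gh, oh)] = summarize_crosslag(draws, gh, oh)
        paths["crosslag_estimates"] = save_json(
            [e.to_dict() for e in estimates.values()], out / "crosslag_estimates.json")
        graph = assemble_graph(estimates)
        paths["graph"] = save_json(graph.to_dict(), out / "graph.json")
        record("fit_var", paths)
    except Exception as exc:  # stage failure: record and stop, keep artifacts
        manifest["failure"] = {
            "stage": f"after {manifest['stages'][-1] if manifest['stages'] else 'start'}",
            "error": f"{type(exc).__name__}: {exc}",
        }
        log.error("study failed: %s", manifest["failure"])

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
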