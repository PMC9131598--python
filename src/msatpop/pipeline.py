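"""End-to-end orchestration: input -> clonality -> diversity -> differentiation
-> ordination -> pooling -> ABC, with seed control and a run manifest.

Each stage writes its table(s) into the output directory and registers them
in manifest.json; a stage failure aborts the run with the stage name while
earlier outputs are preserved. A single master seed drives every stochastic
stage through fixed offsets, so identical configs give identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .abc import abc_analysis, summarize
from .clonality import collapse_mll, identify_mlg
from .fca import allele_count_coding, correspondence_analysis, population_centroids
from .genotype_io import pool_populations, read_genepop, write_genepop
from .popstats import diversity_table, fst_matrix
from .scenario import load_scenario, scenario13, scenario13_alternative
from .simulate import SimConfig
from .synthetic import MEADOW_TO_DEME, make_study_like

log = logging.getLogger("msatpop")

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {"synth": 0, "stats": 1, "fst": 2, "abc": 3}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see configs in examples/)."""

    outdir: str
    input: str | None = None  # genepop path; None -> synthesize
    synth_scale: float = 0.25
    mll_threshold: int = 2
    B: int = 10000
    alpha: float = 0.05
    pooling: dict[str, str] = field(default_factory=lambda: dict(MEADOW_TO_DEME))
    drop: list[str] = field(default_factory=lambda: ["CYP"])
    scenario_files: list[str] = field(default_factory=list)  # default: built-ins
    abc_rows_per_scenario: int = 2000
    abc_retain_fraction: float = 0.01
    abc_n_delta: int = 500
    abc_use_mll_representatives: bool = True
    abc_sizes_scale: float = 1.0  # shrink simulated sample sizes for speed
    predictive_reps: int = 0
    fca_axes: int = 3
    seed: int = 1
    stages: list[str] | None = None  # None -> all stages

    ALL_STAGES = ("clonality", "diversity", "differentiation", "ordination", "abc")

    def enabled(self, stage: str) -> bool:
        return self.stages is None or stage in self.stages

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        # drop-in pooling maps may arrive as non-plain dicts
        d["pooling"] = dict(d["pooling"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s ...", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["failed_stage"] = name
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.time() - self.t0)
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to outdir)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=[
            logging.StreamHandler(sys.stderr),
            logging.FileHandler(out / "run.log", mode="w"),
        ],
        force=True,
    )
    logging.getLogger("msprime").setLevel(logging.WARNING)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "outputs": {},
    }
    cfg.to_yaml(out / "config.yaml")

    with _stage(manifest, "input"):
        if cfg.input is None:
            bundle = make_study_like(
                seed=cfg.seed + SEED_OFFSETS["synth"], scale=cfg.synth_scale
            )
            gm = bundle.corrupted
            write_genepop(gm, out / "input.gen", title="synthetic study-shaped data")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {"params": bundle.params, "ledger": {
                        k: v for k, v in bundle.ledger.items() if k != "changes"
                    }},
                    fh, indent=2, default=str,
                )
            manifest["outputs"]["truth"] = "truth.json"
        else:
            gm = read_genepop(cfg.input)
        manifest["outputs"]["input"] = "input.gen" if cfg.input is None else cfg.input
        manifest["n_samples"] = gm.n_samples
        manifest["n_loci"] = gm.n_loci

    coll = None
    if cfg.enabled("clonality") or (cfg.enabled("abc") and cfg.abc_use_mll_representatives):
        with _stage(manifest, "clonality"):
            part = identify_mlg(gm)
            coll = collapse_mll(part, gm, cfg.mll_threshold)
            coll.counts().to_csv(out / "clonality.tsv", sep="\t", index=False)
            coll.to_tsv(out / "mll_assignment.tsv")
            manifest["outputs"]["clonality"] = "clonality.tsv"
            manifest["n_mlg"] = coll.n_mlg
            manifest["n_mll"] = coll.n_mll

    if cfg.enabled("diversity"):
      with _stage(manifest, "diversity"):
        div = diversity_table(
            gm, B=cfg.B, alpha=cfg.alpha, seed=cfg.seed + SEED_OFFSETS["stats"]
        )
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        manifest["outputs"]["diversity"] = "diversity.tsv"

    if cfg.enabled("differentiation"):
      with _stage(manifest, "differentiation"):
        fm = fst_matrix(
            gm, B=cfg.B, alpha=cfg.alpha, seed=cfg.seed + SEED_OFFSETS["fst"]
        )
        fm.to_tsv(out / "fst_matrix.tsv")
        fm.pvalues.to_csv(out / "fst_pvalues.tsv", sep="\t")
        manifest["outputs"]["fst"] = "fst_matrix.tsv"
        manifest["fst_alpha_adjusted"] = fm.alpha_adjusted

    if cfg.enabled("ordination"):
      with _stage(manifest, "ordination"):
        table = allele_count_coding(gm)
        res = correspondence_analysis(table, k_axes=cfg.fca_axes)
        res.to_tsv(out / "fca_coordinates.tsv")
        population_centroids(res, gm.pop_labels).to_csv(
            out / "fca_centroids.tsv", sep="\t"
        )
        manifest["outputs"]["fca"] = "fca_coordinates.tsv"
        manifest["fca_percent_inertia"] = [float(x) for x in res.percent_inertia]
        try:
            from .fca import plot_ordination

            plot_ordination(res, gm.pop_labels, out / "fca.png")
            manifest["outputs"]["fca_plot"] = "fca.png"
        except ImportError:
            log.info("matplotlib unavailable; skipping ordination plot")

    if cfg.enabled("abc"):
      with _stage(manifest, "abc"):
        if cfg.abc_use_mll_representatives:
            gm_abc = gm.subset(coll.representatives())
        else:
            gm_abc = gm
        pooled = pool_populations(gm_abc, cfg.pooling, drop=cfg.drop)
        if cfg.scenario_files:
            scens = {s.name: s for s in map(load_scenario, cfg.scenario_files)}
        else:
            s13, alt = scenario13(), scenario13_alternative()
            scens = {s13.name: s13, alt.name: alt}
        demes = pooled.populations
        sizes = {
            d: max(2, round(sum(p == d for p in pooled.pop_labels) * cfg.abc_sizes_scale))
            for d in demes
        }
        simcfg = SimConfig(sample_sizes=sizes, n_loci=pooled.n_loci)
        obs = summarize(pooled, demes=demes)
        result = abc_analysis(
            obs,
            scens,
            simcfg,
            n_per_scenario=cfg.abc_rows_per_scenario,
            retain_fraction=cfg.abc_retain_fraction,
            n_delta=cfg.abc_n_delta,
            seed=cfg.seed + SEED_OFFSETS["abc"],
            predictive_reps=cfg.predictive_reps,
        )
        with open(out / "abc_result.json", "w") as fh:
            fh.write(result.to_json())
        result.reference.save(out / "reference_table.tsv")
        manifest["outputs"]["abc"] = "abc_result.json"
        manifest["outputs"]["reference_table"] = "reference_table.tsv"
        manifest["abc_best_scenario"] = result.best_scenario(
            "direct" if result.logistic_degenerate else "logistic"
        )

    manifest["n_stage_outputs"] = len(manifest["outputs"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
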