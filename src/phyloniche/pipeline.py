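"""End-to-end orchestration with reproducible configuration and manifests.

Stages (each reads/writes only declared files under the run directory):

- ``simulate``  : synthetic study-shaped dataset (raster, occurrences,
  metadata, trees, true parameters)
- ``envspace``  : background PCA, occurrence filtering/deduplication, niches
- ``overlap``   : pairwise Schoener's D, overlap regressions, range inclusion
- ``simmap``    : example stochastic maps and fitted Mk models
- ``evofit``    : replicated six-model AICc-weight analysis
- ``report``    : render the three result tables from cached stage outputs

A single root seed deterministically derives per-stage substreams, so a rerun
with the same configuration and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import charmap, envspace as es, evomodels as em, io as pio
from . import overlap as ov, synthetic as syn

__all__ = ["RunConfig", "full_run", "stage_simulate", "stage_envspace",
           "stage_overlap", "stage_simmap", "stage_evofit", "stage_report"]

_STAGE_IDS = {"simulate": 1, "envspace": 2, "overlap": 3, "simmap": 4,
              "evofit": 5, "report": 6}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; everything is relative to ``outdir``."""

    outdir: str = "run"
    seed: int = 0
    # input files (produced by `simulate` or supplied by the user)
    raster: str = "raster.csv"
    plant_occurrences: str = "plant_occurrences.csv"
    plant_metadata: str = "plant_metadata.csv"
    pollinator_occurrences: str = "pollinator_occurrences.csv"
    pollinator_metadata: str = "pollinator_metadata.csv"
    trees: str = "trees.nwk"
    # synthetic preset
    preset: str = "study-shape"
    n_species: int = 35
    n_pixels: int = 3458
    # occurrence filters
    precision_km: float = 10.0
    min_records: int = 5
    min_pixels: int = 5
    pollinator_min_counts: bool = False
    # overlap analysis
    grid_resolution: int = 100
    corrected: bool = True
    # character mapping
    root_treatment: str = "fitzjohn"
    mk_restarts: int = 2
    # evolutionary models
    n_iterations: int = 50
    restarts: int = 2
    # reporting
    report_decimals: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _update_manifest(cfg: RunConfig, stage: str, inputs, outputs, seconds):
    from . import __version__

    path = cfg.path("manifest.json")
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.setdefault("version", __version__)
    manifest["config"] = dataclasses.asdict(cfg)
    manifest.setdefault("stages", {})
    manifest["stages"][stage] = {
        "inputs": {str(p): _sha256(cfg.path(p)) for p in inputs
                   if cfg.path(p).exists()},
        "outputs": {str(p): _sha256(cfg.path(p)) for p in outputs},
        "seconds": round(seconds, 3),
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _stage(name):
    def wrap(fn):
        def run(cfg: RunConfig, **kw):
            Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
            t0 = time.perf_counter()
            inputs, outputs = fn(cfg, **kw)
            _update_manifest(cfg, name, inputs, outputs,
                             time.perf_counter() - t0)
            return outputs
        run.__name__ = f"stage_{name}"
        return run
    return wrap


# ------------------------------------------------------------------ stages
@_stage("simulate")
def stage_simulate(cfg: RunConfig):
    if cfg.preset != "study-shape":
        raise ValueError(f"unknown preset {cfg.preset!r}")
    scfg = syn.SyntheticConfig(seed=cfg.seed, n_species=cfg.n_species,
                               n_taxa=cfg.n_species, n_pixels=cfg.n_pixels,
                               n_trees=max(cfg.n_iterations, 1))
    ds = syn.generate_dataset(scfg)
    pio.write_raster(ds.raster, cfg.path(cfg.raster))
    pio.write_occurrences(ds.plant_occurrences, cfg.path(cfg.plant_occurrences))
    pio.write_metadata(ds.plant_occurrences.metadata, cfg.path(cfg.plant_metadata))
    pio.write_occurrences(ds.pollinator_occurrences,
                          cfg.path(cfg.pollinator_occurrences))
    pio.write_metadata(ds.pollinator_occurrences.metadata,
                       cfg.path(cfg.pollinator_metadata))
    pio.write_trees(ds.trees, cfg.path(cfg.trees))
    pio.write_json(ds.true_params, cfg.path("true_params.json"))
    return [], [cfg.raster, cfg.plant_occurrences, cfg.plant_metadata,
                cfg.pollinator_occurrences, cfg.pollinator_metadata,
                cfg.trees, "true_params.json"]


def _clean_occurrences(cfg: RunConfig, raster, which: str):
    occ = pio.read_occurrences(cfg.path(getattr(cfg, f"{which}_occurrences")),
                               cfg.path(getattr(cfg, f"{which}_metadata")))
    enforce = which == "plant" or cfg.pollinator_min_counts
    occ, log = es.apply_filters(occ, raster, cfg.precision_km,
                                cfg.min_records, cfg.min_pixels,
                                enforce_min_counts=enforce)
    return es.dedupe_per_pixel(occ), log


@_stage("envspace")
def stage_envspace(cfg: RunConfig):
    raster = pio.read_raster(cfg.path(cfg.raster))
    space = es.fit_env_space(raster)
    space.to_json(cfg.path("env_space.json"))
    logs = {}
    outputs = ["env_space.json"]
    for which in ("plant", "pollinator"):
        occ, logs[which] = _clean_occurrences(cfg, raster, which)
        niches = es.species_niche(occ, space, raster)
        es.niches_to_frame(niches).to_csv(
            cfg.path(f"{which}_niches.csv"), index=False)
        pio.write_occurrences(occ, cfg.path(f"{which}_occurrences_clean.csv"))
        outputs += [f"{which}_niches.csv", f"{which}_occurrences_clean.csv"]
    pio.write_json(logs, cfg.path("filter_log.json"))
    return ([cfg.raster, cfg.plant_occurrences, cfg.pollinator_occurrences],
            outputs + ["filter_log.json"])


def _load_clean(cfg: RunConfig, raster, which: str):
    occ = pio.read_occurrences(cfg.path(f"{which}_occurrences_clean.csv"),
                               cfg.path(getattr(cfg, f"{which}_metadata")))
    space = es.EnvSpace.from_json(cfg.path("env_space.json"))
    niches = es.species_niche(occ, space, raster)
    return occ, space, niches


@_stage("overlap")
def stage_overlap(cfg: RunConfig):
    raster = pio.read_raster(cfg.path(cfg.raster))
    outputs = []
    group_niches = {}
    for which, label in (("plant", "pollination"), ("pollinator", "group")):
        occ, space, niches = _load_clean(cfg, raster, which)
        meta = occ.subset_metadata()
        pairs = ov.pairwise_overlap(niches, meta, space,
                                    R=cfg.grid_resolution,
                                    corrected=cfg.corrected)
        pairs.to_csv(cfg.path(f"{which}_overlap_pairs.csv"), index=False)
        fits = ov.fit_overlap_models(pairs, group_label=label)
        ov.overlap_models_to_frame(fits).to_csv(
            cfg.path(f"{which}_overlap_models.csv"), index=False)
        outputs += [f"{which}_overlap_pairs.csv", f"{which}_overlap_models.csv"]
        group_niches[which] = (niches, meta)

    # range inclusion of each plant in its pollinator functional group
    pol_niches, pol_meta = group_niches["pollinator"]
    by_group = {}
    for n in pol_niches:
        g = pol_meta.set_index("species").loc[n.species, "pollination_mode"]
        by_group.setdefault(g, []).append(n)
    report = {}
    plant_niches, plant_meta = group_niches["plant"]
    modes = plant_meta.set_index("species")["pollination_mode"]
    for n in plant_niches:
        mode = modes.get(n.species, "unknown")
        if mode == "hummingbird":
            group = by_group.get("hummingbird", [])
        elif mode == "bat":
            group = by_group.get("bat", [])
        else:                      # mixed or unknown: all pollinators
            group = [x for g in by_group.values() for x in g]
        if group:
            report[n.species] = ov.range_inclusion(n, group)
    pio.write_json(report, cfg.path("range_inclusion.json"))
    return (["env_space.json", "plant_occurrences_clean.csv",
             "pollinator_occurrences_clean.csv"],
            outputs + ["range_inclusion.json"])


@_stage("simmap")
def stage_simmap(cfg: RunConfig):
    raster = pio.read_raster(cfg.path(cfg.raster))
    occ, _, niches = _load_clean(cfg, raster, "plant")
    meta = occ.subset_metadata()
    trees = pio.read_trees(cfg.path(cfg.trees))
    keep = sorted(set(trees[0].tip_labels) & {n.species for n in niches})
    tree = trees[0] if set(keep) == set(trees[0].tip_labels) \
        else trees[0].prune_to(keep)
    rng = np.random.default_rng([cfg.seed, _STAGE_IDS["simmap"]])
    models = {}
    outputs = []
    for character, constraint, states, priors in (
        ("island", "SYM", charmap.ISLAND_STATES,
         charmap.delta_priors(charmap.assign_single_island(meta, rng),
                              charmap.ISLAND_STATES)),
        ("pollination", "ARD", charmap.POLLINATION_STATES,
         charmap.build_tip_priors(meta)),
    ):
        model = charmap.fit_mk(tree, priors, constraint, states,
                               cfg.root_treatment, restarts=cfg.mk_restarts,
                               seed=int(rng.integers(2 ** 31)))
        smap = charmap.sample_stochastic_map(tree, model, priors, rng)
        smap.to_frame().to_csv(
            cfg.path(f"simmap_{character}_segments.csv"), index=False)
        with open(cfg.path(f"simmap_{character}.tre"), "w") as fh:
            fh.write(smap.to_annotated_newick() + "\n")
        models[character] = {
            "constraint": constraint, "states": list(states),
            "Q": model.Q.tolist(), "log_likelihood": model.log_likelihood,
            "root_treatment": model.root_treatment,
        }
        outputs += [f"simmap_{character}_segments.csv",
                    f"simmap_{character}.tre"]
    pio.write_json(models, cfg.path("mk_models.json"))
    return ([cfg.trees, "plant_occurrences_clean.csv"],
            outputs + ["mk_models.json"])


@_stage("evofit")
def stage_evofit(cfg: RunConfig):
    raster = pio.read_raster(cfg.path(cfg.raster))
    occ, space, _ = _load_clean(cfg, raster, "plant")
    trees = pio.read_trees(cfg.path(cfg.trees))
    rcfg = em.ReplicateConfig(
        n_iterations=cfg.n_iterations, seed=cfg.seed, restarts=cfg.restarts,
        mk_restarts=cfg.mk_restarts, root_treatment=cfg.root_treatment)
    res = em.run_replicates(trees, occ, occ.subset_metadata(), space, rcfg,
                            raster=raster)
    res.iterations.to_csv(cfg.path("evo_iteration_fits.csv"), index=False)
    res.summary.to_csv(cfg.path("evo_weight_summary.csv"), index=False)
    pio.write_json({"failures": res.failures},
                   cfg.path("evo_failures.json"))
    return ([cfg.trees, "plant_occurrences_clean.csv", "env_space.json"],
            ["evo_iteration_fits.csv", "evo_weight_summary.csv",
             "evo_failures.json"])


def _render_overlap_table(path_in, path_out, decimals):
    df = pd.read_csv(path_in)
    num = df.select_dtypes(include=[float]).columns
    df[num] = df[num].round(decimals)
    df.to_csv(path_out, index=False)


@_stage("report")
def stage_report(cfg: RunConfig):
    d = cfg.report_decimals
    _render_overlap_table(cfg.path("plant_overlap_models.csv"),
                          cfg.path("table1_plant_overlap.csv"), d)
    _render_overlap_table(cfg.path("pollinator_overlap_models.csv"),
                          cfg.path("table2_pollinator_overlap.csv"), d)
    summary = pd.read_csv(cfg.path("evo_weight_summary.csv"))
    summary["cell"] = (summary["mean_weight"].round(d).astype(str)
                       + " [" + summary["ci_low"].round(d).astype(str)
                       + "-" + summary["ci_high"].round(d).astype(str) + "]")
    order = [em.TRAIT_SET_LABELS[t] for t in em.DEFAULT_TRAIT_SETS]
    table3 = (summary.pivot(index="trait_set", columns="model", values="cell")
              .reindex([t for t in order
                        if t in set(summary["trait_set"])])
              .reset_index())
    cols = ["trait_set"] + [c for c in ("BM1", "BM3", "BM4", "OU1", "OU3",
                                        "OU4") if c in table3.columns]
    table3[cols].to_csv(cfg.path("table3_mean_aicc_weights.csv"), index=False)
    return (["plant_overlap_models.csv", "pollinator_overlap_models.csv",
             "evo_weight_summary.csv"],
            ["table1_plant_overlap.csv", "table2_pollinator_overlap.csv",
             "table3_mean_aicc_weights.csv"])


def full_run(cfg: RunConfig):
    """Chain all stages and return the list of report files."""
    stage_simulate(cfg)
    stage_envspace(cfg)
    stage_overlap(cfg)
    stage_simmap(cfg)
    stage_evofit(cfg)
    return stage_report(cfg)
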