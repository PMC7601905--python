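"""Seeded end-to-end pipeline runs with a reproducibility manifest.

Stages run in a fixed order (simulate/load -> preprocess -> screen ->
ensemble -> vote -> interaction), each writing delimited text artifacts into
a write-once output directory. A JSON manifest records the configuration,
the derived per-stage seeds and a SHA-256 digest of every output, plus one
overall manifest hash: identical config + master seed must reproduce the
hash bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import interaction as inter
from . import voting
from .config import PANELS, SimulationConfig, resolve_panel, spawn_seeds
from .preprocess import censor_frame, quantify_plate
from .quartiles import screen_panel
from .simulate import CohortDataset, generate_cohorts, generate_plate
from .survival import km_estimate

log = logging.getLogger("saspsurv")

STAGES = ("simulate", "preprocess", "screen", "ensemble", "vote",
          "interaction")
FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one input source.

    Either ``simulation`` (a SimulationConfig) or ``input_paths`` (mapping
    cohort label -> {patients, analytes} CSV paths) must be provided.
    """

    outdir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_paths: dict | None = None
    panel: str | list = "p8"
    ensembles: list = field(default_factory=lambda: [
        {"cohort": "RTBT2", "panel": "p8"},
        {"cohort": "RT3", "panel": "p8"},
    ])
    n_pairs: int = 3000
    n_boot: int = 1000
    max_models: int = 25
    hr_min: float = 3.0
    p_max: float = 0.05
    subsample_fraction: float = 70.0
    voting_rule: str = "ternary"   # consensus rule for interaction strata
    horizon: float = 5.0
    with_plate: bool = True        # emit + QC a synthetic plate fixture

    def validate(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError(
                "provide exactly one of simulation config or input paths")
        if self.voting_rule not in ("binary", "ternary"):
            raise ValueError("voting_rule must be 'binary' or 'ternary'")
        for entry in self.ensembles:
            resolve_panel(entry["panel"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def export_km(curve, path: Path) -> None:
    """KM curve as CSV (time, at_risk, events, survival)."""
    df = pd.DataFrame({"time": curve.times, "at_risk": curve.at_risk,
                       "events": curve.n_events, "survival": curve.survival})
    _write_csv(df, path)


def read_km(path: Path):
    df = pd.read_csv(path)
    from .survival import KMCurve
    return KMCurve(df["time"].to_numpy(), df["survival"].to_numpy(),
                   df["at_risk"].to_numpy(), df["events"].to_numpy())


class PipelineRun:
    """Stage-wise executor over a shared output directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        names = ["simulate", "plate", "screen"] + \
            [f"ensemble_{e['cohort']}" for e in config.ensembles]
        seeds = spawn_seeds(config.seed, len(names))
        self.stage_seeds = dict(zip(names, seeds))
        self.cohorts: list[CohortDataset] | None = None

    # -- stage: simulate / load ------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.simulation is not None:
            sim = dataclasses.replace(cfg.simulation,
                                      seed=self.stage_seeds["simulate"])
            self.cohorts = generate_cohorts(sim)
        else:
            self.cohorts = [
                CohortDataset.read(label, paths["patients"],
                                   paths["analytes"])
                for label, paths in cfg.input_paths.items()]
        for cohort in self.cohorts:
            cohort.patients = censor_frame(cohort.patients,
                                           self.config.horizon)
            cohort.write(self.outdir / f"patients_{cohort.label}.csv",
                         self.outdir / f"analytes_{cohort.label}.csv")

    def _load_cohorts(self) -> list[CohortDataset]:
        if self.cohorts is not None:
            return self.cohorts
        labels = (list(self.config.input_paths) if self.config.input_paths
                  else list((self.config.simulation or SimulationConfig())
                            .group_sizes))
        cohorts = []
        for label in labels:
            ppath = self.outdir / f"patients_{label}.csv"
            apath = self.outdir / f"analytes_{label}.csv"
            if not ppath.exists() or not apath.exists():
                raise FileNotFoundError(
                    f"stage dependency missing: {ppath} (run 'simulate' "
                    "first)")
            cohorts.append(CohortDataset.read(label, ppath, apath))
        self.cohorts = cohorts
        return cohorts

    # -- stage: preprocess ------------------------------------------------
    def stage_preprocess(self) -> None:
        if not self.config.with_plate:
            return
        sim = self.config.simulation or SimulationConfig()
        sim = dataclasses.replace(sim, seed=self.stage_seeds["plate"])
        plate = generate_plate(sim, analytes=list(sim.analyte_names[:4]))
        _write_csv(plate, self.outdir / "plate_raw.csv")
        tidy, report = quantify_plate(plate)
        _write_csv(tidy, self.outdir / "plate_quantified.csv")
        _write_csv(report.flagged, self.outdir / "plate_qc_flagged.csv")
        _write_csv(report.cv_by_group, self.outdir / "plate_qc_cv.csv")

    # -- stage: screen -----------------------------------------------------
    def stage_screen(self) -> None:
        cohorts = self._load_cohorts()
        table = screen_panel(cohorts, list(cohorts[0].analyte_names))
        _write_csv(table, self.outdir / "quartile_screen.csv")

    # -- stage: ensemble ---------------------------------------------------
    def stage_ensemble(self) -> None:
        cohorts = {c.label: c for c in self._load_cohorts()}
        cfg = self.config
        for entry in cfg.ensembles:
            label = entry["cohort"]
            if label not in cohorts:
                raise ValueError(f"ensemble cohort {label} not in inputs")
            others = [c for lbl, c in cohorts.items() if lbl != label]
            records = ens.run_ensemble(
                cohorts[label], entry["panel"], n_pairs=cfg.n_pairs,
                n_boot=cfg.n_boot, max_models=cfg.max_models,
                hr_min=cfg.hr_min, p_max=cfg.p_max,
                subsample_fraction=cfg.subsample_fraction,
                validation_cohorts=others,
                seed=self.stage_seeds[f"ensemble_{label}"])
            log.info("ensemble %s: %d models selected", label, len(records))
            _write_csv(ens.records_to_table(records),
                       self.outdir / f"models_{label}.csv")
            ens.records_to_jsonl(records,
                                 self.outdir / f"models_{label}.jsonl")

    # -- stage: vote -------------------------------------------------------
    def stage_vote(self) -> None:
        cohorts = {c.label: c for c in self._load_cohorts()}
        for entry in self.config.ensembles:
            label = entry["cohort"]
            mpath = self.outdir / f"models_{label}.jsonl"
            if not mpath.exists():
                raise FileNotFoundError(
                    f"stage dependency missing: {mpath} (run 'ensemble' "
                    "first)")
            models = ens.load_models_jsonl(mpath)
            if not models:
                continue
            analytes = pd.concat([c.analytes for c in cohorts.values()])
            matrix = voting.build_vote_matrix(models, analytes)
            matrix.to_frame().to_csv(
                self.outdir / f"votes_{label}.csv")
            assignments = voting.consensus(matrix)
            _write_csv(voting.consensus_frame(assignments),
                       self.outdir / f"consensus_{label}.csv")
            summary = voting.confidence_summary(assignments)
            (self.outdir / f"confidence_{label}.json").write_text(
                json.dumps(summary, sort_keys=True, indent=1))

    # -- stage: interaction ------------------------------------------------
    def stage_interaction(self) -> None:
        cohorts = {c.label: c for c in self._load_cohorts()}
        stage3 = [c for c in cohorts.values()
                  if (c.patients["stage"] == "III").all()]
        if not stage3:
            log.info("no stage III cohorts; interaction stage skipped")
            return
        patients = pd.concat([c.patients for c in stage3], ignore_index=True)
        analytes = pd.concat([c.analytes for c in stage3])
        mpath = self.outdir / "models_RT3.jsonl"
        if not mpath.exists():
            raise FileNotFoundError(
                f"stage dependency missing: {mpath} (run 'ensemble' first)")
        models = ens.load_models_jsonl(mpath)
        if not models:
            log.info("no RT3 models selected; interaction stage skipped")
            return
        tables = []
        for model in models:
            labels = ens.dichotomize(model, analytes)
            res = inter.stratified_bt_effect(patients, labels,
                                             n_models=len(models))
            tables.append(inter.strata_table(res, model_id=model.model_id))
        _write_csv(pd.concat(tables, ignore_index=True),
                   self.outdir / "bt_strata_per_model.csv")
        matrix = voting.build_vote_matrix(models, analytes)
        assignments = voting.consensus(matrix)
        if self.config.voting_rule == "ternary":
            labels = np.array([f"SASP_{a.ternary_label}"
                               for a in assignments])
        else:
            labels = np.array([f"SASP_{a.binary_label}"
                               for a in assignments])
        res = inter.stratified_bt_effect(patients, labels,
                                         n_models=len(models))
        _write_csv(inter.strata_table(res, model_id="consensus"),
                   self.outdir / "bt_strata_consensus.csv")
        # multifactor stage x SASP x treatment summary over all cohorts
        all_pat = pd.concat([c.patients for c in cohorts.values()],
                            ignore_index=True)
        all_ana = pd.concat([c.analytes for c in cohorts.values()])
        all_assign = voting.consensus(voting.build_vote_matrix(models,
                                                               all_ana))
        all_labels = np.array([f"SASP_{a.ternary_label}"
                               for a in all_assign])
        _write_csv(inter.multifactor_strata(all_pat, all_labels),
                   self.outdir / "multifactor_strata.csv")
        for c in cohorts.values():
            km = km_estimate(c.patients["time"].to_numpy(),
                             c.patients["event"].to_numpy())
            export_km(km, self.outdir / f"km_{c.label}.csv")


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute stages in order and write/return the run manifest."""
    run = PipelineRun(config)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        method = getattr(run, f"stage_{stage}")
        log.info("running stage %s", stage)
        try:
            method()
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    outputs = sorted(p for p in run.outdir.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    file_hashes = {p.name: _sha256(p) for p in outputs}
    hashed_config = {k: v for k, v in config.to_dict().items()
                     if k != "outdir"}  # location doesn't affect content
    config_json = json.dumps(hashed_config, sort_keys=True, default=str)
    manifest_hash = hashlib.sha256(
        (config_json + json.dumps(file_hashes, sort_keys=True)).encode()
    ).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": run.stage_seeds,
        "files": file_hashes,
        "manifest_hash": manifest_hash,
        "panels": {k: list(v) for k, v in PANELS.items()},
    }
    (run.outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str))
    return manifest
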