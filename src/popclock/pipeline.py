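"""End-to-end pipeline orchestration with a reproducibility manifest.

A run is described by a :class:`RunConfig` (typically loaded from YAML):
input matrices or a synthetic-trajectory spec, stage toggles, thresholds
and one master seed.  Stages execute in dependency order

    simulate/load -> preprocess -> [saturate] -> fit_time -> predict_time
    -> timer_genes

and every randomized stage draws its own seed derived from the master
seed and the stage name, so toggling one stage never shifts another
stage's randomness.  A manifest JSON records inputs, parameters, derived
seeds and SHA-256 checksums of all outputs; re-running from the same
manifest reproduces every numeric output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import exprio, saturation, simulate, timemodel

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "config_from_manifest"]

_ALLOWED_KEYS = {
    "seed", "outdir", "stages", "inputs", "trajectory", "thresholds",
}
_ALLOWED_STAGES = ["simulate", "preprocess", "saturate", "fit_time",
                   "predict_time", "timer_genes"]
_ALLOWED_THRESHOLDS = {
    "min_level": float, "min_samples": int, "bulk_pcc_cutoff": float,
    "bulk_p_cutoff": float, "sc_pcc_cutoff": float, "sc_p_cutoff": float,
    "n_perm": int, "max_combos": int, "saturation_epsilon": float,
    "n_components": int, "scaled": bool,
}
_DEFAULT_THRESHOLDS = {
    "min_level": 0.5, "min_samples": 8, "bulk_pcc_cutoff": 0.6,
    "bulk_p_cutoff": 0.003, "sc_pcc_cutoff": 0.4, "sc_p_cutoff": 0.001,
    "n_perm": 1000, "max_combos": 30, "saturation_epsilon": 0.01,
    "n_components": 2, "scaled": True,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(master_seed)) & 0x7FFFFFFF


@dataclass
class RunConfig:
    seed: int
    outdir: str
    stages: list[str]
    inputs: dict[str, str] = field(default_factory=dict)
    trajectory: dict[str, Any] = field(default_factory=dict)
    thresholds: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = cfg.get("stages", ["simulate", "preprocess", "fit_time",
                                    "predict_time", "timer_genes"])
        bad = [s for s in stages if s not in _ALLOWED_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        thresholds = dict(_DEFAULT_THRESHOLDS)
        for k, v in cfg.get("thresholds", {}).items():
            if k not in _ALLOWED_THRESHOLDS:
                raise ValueError(f"unknown threshold {k!r}")
            want = _ALLOWED_THRESHOLDS[k]
            if want is bool and not isinstance(v, bool):
                raise ValueError(f"threshold {k!r} must be a bool")
            if want in (int, float) and isinstance(v, bool) or not isinstance(v, (int, float, bool)):
                raise ValueError(f"threshold {k!r} has invalid type {type(v).__name__}")
            thresholds[k] = want(v)
        return cls(
            seed=int(cfg["seed"]),
            outdir=str(cfg["outdir"]),
            stages=list(stages),
            inputs=dict(cfg.get("inputs", {})),
            trajectory=dict(cfg.get("trajectory", {})),
            thresholds=thresholds,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_from_manifest(manifest: dict | str | Path, outdir: str | Path) -> RunConfig:
    """Reconstruct a RunConfig from a manifest (dict or path) so a run can
    be reproduced into a fresh output directory."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    return RunConfig.from_dict(
        {
            "seed": manifest["seed"],
            "outdir": str(outdir),
            "stages": manifest["stages"],
            "inputs": manifest.get("inputs", {}),
            "trajectory": manifest.get("trajectory", {}),
            "thresholds": manifest.get("thresholds", {}),
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g", index=False)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": config.stages,
        "thresholds": thr,
        "derived_seeds": {s: derive_seed(config.seed, s) for s in config.stages},
        "inputs": config.inputs,
        "trajectory": config.trajectory,
        "outputs": {},
    }
    done: set[str] = set()

    bulk = sc = truth = None
    if "simulate" in config.stages:
        spec = simulate.TrajectorySimSpec(
            seed=derive_seed(config.seed, "simulate"), **config.trajectory
        )
        sim = simulate.simulate_trajectory(spec)
        bulk, sc, truth = sim.bulk, sim.sc, sim.true_cell_times
        exprio.write_matrix(bulk, outdir / "bulk.tsv")
        exprio.write_matrix(sc, outdir / "sc.tsv")
        truth.to_frame().to_csv(outdir / "true_times.tsv", sep="\t",
                                float_format="%.12g")
        done.add("simulate")
    elif config.inputs:
        bulk = exprio.read_matrix(config.inputs["bulk"],
                                  sample_meta=config.inputs.get("bulk_meta"))
        sc = exprio.read_matrix(config.inputs["sc"],
                                sample_meta=config.inputs.get("sc_meta"))
        done.add("simulate")
    else:
        raise ValueError("no inputs: enable the simulate stage or provide input paths")

    sc_filtered = None
    if "preprocess" in config.stages:
        sc_norm = exprio.quantile_normalize(sc)
        min_samp = min(int(thr["min_samples"]), sc.shape[1])
        sc_filtered = exprio.filter_expressed(
            sc_norm, min_level=thr["min_level"], min_samples=min_samp
        )
        done.add("preprocess")

    if "saturate" in config.stages:
        if sc_filtered is None:
            raise ValueError("saturate requires the preprocess stage")
        ref = bulk.values.mean(axis=1)
        sat = saturation.sampling_saturation(
            sc, ref, max_combos=int(thr["max_combos"]),
            min_level=thr["min_level"], min_samples=int(thr["min_samples"]),
            seed=derive_seed(config.seed, "saturate"),
        )
        _write_tsv(saturation.result_to_frame(sat), outdir / "saturation.tsv")
        done.add("saturate")

    model = None
    if "fit_time" in config.stages:
        if sc_filtered is None:
            raise ValueError("fit_time requires the preprocess stage")
        bulk_deg = timemodel.timer_genes(
            bulk, bulk.times(), pcc_cutoff=thr["bulk_pcc_cutoff"],
            p_cutoff=thr["bulk_p_cutoff"], n_perm=int(thr["n_perm"]),
            seed=derive_seed(config.seed, "fit_time"),
        ).selected_genes
        model = timemodel.fit_pls_time(
            exprio.log_transform(bulk),
            sc_expressed_genes=sc_filtered.gene_ids,
            cp_deg_genes=bulk_deg,
            n_components=int(thr["n_components"]),
            scaled=bool(thr["scaled"]),
        )
        model.to_json(outdir / "time_model.json")
        done.add("fit_time")

    preds = None
    if "predict_time" in config.stages:
        if model is None:
            raise ValueError("predict_time requires the fit_time stage")
        preds = timemodel.predict_sc_time(model, exprio.log_transform(sc))
        df = pd.DataFrame(
            {
                "cell_id": [p.cell_id for p in preds],
                "raw_T": [p.raw_T for p in preds],
                "t": [p.t for p in preds],
                "PLSC1": [p.sc_scores[0] for p in preds],
                "PLSC2": [p.sc_scores[1] for p in preds],
            }
        )
        _write_tsv(df, outdir / "sc_times.tsv")
        done.add("predict_time")

    if "timer_genes" in config.stages:
        if preds is None:
            raise ValueError("timer_genes requires the predict_time stage")
        t_vec = np.array([p.t for p in preds])
        tg = timemodel.timer_genes(
            exprio.log_transform(sc_filtered if sc_filtered is not None else sc),
            t_vec, pcc_cutoff=thr["sc_pcc_cutoff"], p_cutoff=thr["sc_p_cutoff"],
            n_perm=int(thr["n_perm"]),
            seed=derive_seed(config.seed, "timer_genes"),
            class_label="t-gene",
        )
        _write_tsv(tg.table, outdir / "timer_genes.tsv")
        done.add("timer_genes")

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
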