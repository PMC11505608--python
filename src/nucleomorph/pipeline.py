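"""End-to-end run orchestration: simulate/load -> measure -> calibrate ->
phenotype -> summarize -> compare.

A run is described by a JSON config (schema version 1) and writes a run
directory containing ``measurements.csv``, ``calls.csv``, ``calibration.json``,
``summary.csv``, ``comparison.csv`` and ``run_log.json``.  All randomness
derives from the single config seed, so two runs with the same config produce
byte-identical outputs.

Config outline::

    {
      "schema": 1,
      "seed": 1,
      "imaging": {"psf_sigma": 0.25, "noise_sd": 20.0},
      "groups": {
        "control": {"mixture": {"ring": 9, ...}, "replicates": 2, "is_control": true},
        "treated": {"mixture": {...}, "replicates": 2}
      },
      "cascade": {"multipliers": {"invagination": 0.42, ...}},   # optional
      "measure": {"median_radius": 2, ...},                      # optional
      "comparison": {"test": "independent", "direction": "greater"},
      "calibration": "per_replicate"                             # or "global"
    }

Alternatively a group may carry ``"stacks_dir"`` and ``"spacing": [xy, z]``
instead of a mixture, in which case its TIFF stacks are loaded from disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascade import (
    CascadeClassifier,
    calibrate,
    calibration_to_dict,
    default_config,
    summarize,
)
from .phantoms import sample_population
from .shape3d import MeasureConfig, measure_cell, measurements_frame
from .stats import compare_groups
from .volio import SpatialCalibration, read_stack


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def demo_config(seed: int = 1, replicates: int = 3, cells_per_replicate: int = 24) -> dict:
    """A small self-contained demo run: seeded control and knockdown-like groups.

    Replicate compositions are drawn multinomially around each group's
    expected phenotype frequencies (control ~85% normal, treated ~50%
    abnormal), so replicates vary the way biological replicates do while the
    whole config stays a pure function of the seed.
    """
    phenos = ("ring", "diffuse", "punctate", "invagination", "incomplete")
    expected = {
        "control": np.array([0.55, 0.30, 0.05, 0.05, 0.05]),
        "treated": np.array([0.30, 0.20, 0.10, 0.22, 0.18]),
    }
    rng = np.random.default_rng([int(seed), 91])
    groups = {}
    for gname in ("control", "treated"):
        mixes = []
        for _ in range(replicates):
            counts = rng.multinomial(cells_per_replicate, expected[gname])
            mixes.append({p: int(c) for p, c in zip(phenos, counts) if c > 0})
        groups[gname] = {"replicate_mixtures": mixes, "is_control": gname == "control"}
    return {
        "schema": 1,
        "seed": int(seed),
        "imaging": {"psf_sigma": 0.25, "noise_sd": 20.0},
        "groups": groups,
        "comparison": {"test": "independent", "direction": "greater"},
        "calibration": "per_replicate",
    }


def _derived_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([int(master), *path]).generate_state(1)[0] % (2**31))


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _collect_cells(config: dict, measure_cfg: MeasureConfig):
    """Simulate or load every group/replicate; yield measurement + metadata rows."""
    imaging = config.get("imaging", {})
    rows = []
    for gi, (gname, gspec) in enumerate(sorted(config["groups"].items())):
        if "replicate_mixtures" in gspec:
            replicates = len(gspec["replicate_mixtures"])
        else:
            replicates = int(gspec.get("replicates", 1))
        for ri in range(replicates):
            if "mixture" in gspec or "replicate_mixtures" in gspec:
                mixture = (gspec["replicate_mixtures"][ri]
                           if "replicate_mixtures" in gspec else gspec["mixture"])
                seed = _derived_seed(config["seed"], gi, ri)
                cells = sample_population(
                    mixture,
                    seed=seed,
                    psf_sigma=float(imaging.get("psf_sigma", 0.0)),
                    noise_sd=float(imaging.get("noise_sd", 0.0)),
                )
                batch = [(f"{gname}_r{ri}_{c.cell_id}", c.grid) for c in cells]
            elif "stacks_dir" in gspec:
                xy, z = gspec["spacing"]
                cal = SpatialCalibration(pixel_size_xy=float(xy), z_step=float(z))
                paths = sorted(Path(gspec["stacks_dir"]).glob("*.tif*"))
                if not paths:
                    raise FileNotFoundError(f"no TIFF stacks in {gspec['stacks_dir']}")
                batch = [(p.stem, read_stack(p, cal)) for p in paths]
            else:
                raise ValueError(f"group {gname!r} needs a 'mixture' or 'stacks_dir'")
            for cid, grid in batch:
                m = measure_cell(grid, measure_cfg, cell_id=cid)
                rows.append(
                    {
                        "group": gname,
                        "replicate": ri,
                        "is_control": bool(gspec.get("is_control", False)),
                        "measurement": m,
                    }
                )
    return rows


def run_pipeline(config, out_dir) -> Path:
    """Execute a full run and return the run directory."""
    if not isinstance(config, dict):
        config_path = Path(config)
        with _stage("config"):
            config = json.loads(config_path.read_text())
    if config.get("schema", 1) != 1:
        raise PipelineError(f"[config] unsupported schema version {config.get('schema')}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress\n")

    measure_cfg = MeasureConfig(**config.get("measure", {}))
    with _stage("measure"):
        rows = _collect_cells(config, measure_cfg)
    frame = measurements_frame([r["measurement"] for r in rows])
    meta = pd.DataFrame(
        [{k: r[k] for k in ("group", "replicate", "is_control")} for r in rows]
    )
    measurements = pd.concat([meta, frame], axis=1)

    cascade_cfg = default_config(config.get("cascade", {}).get("multipliers"))
    per_replicate = config.get("calibration", "per_replicate") == "per_replicate"
    control_rows = [r for r in rows if r["is_control"]]
    if not control_rows:
        raise PipelineError("[calibrate] no group is flagged 'is_control'")

    calls_records = []
    calibrations = {}
    with _stage("calibrate"):
        if per_replicate:
            reps = sorted({r["replicate"] for r in rows})
            for ri in reps:
                control = [r["measurement"] for r in control_rows if r["replicate"] == ri]
                if not control:
                    raise ValueError(f"replicate {ri} has no control cells")
                calibrations[ri] = calibrate(
                    control, cascade_cfg, provenance=f"control cells, replicate {ri}"
                )
        else:
            cal = calibrate(
                [r["measurement"] for r in control_rows], cascade_cfg,
                provenance="control cells, all replicates",
            )
            calibrations = {ri: cal for ri in sorted({r["replicate"] for r in rows})}

    with _stage("phenotype"):
        clf = CascadeClassifier(cascade_cfg)
        for r in rows:
            clf.calibration_ = calibrations[r["replicate"]]
            clf.thresholds_ = clf.calibration_.thresholds
            call = clf.predict_calls([r["measurement"]])[0]
            calls_records.append(
                {
                    "cell_id": r["measurement"].cell_id,
                    "group": r["group"],
                    "replicate": r["replicate"],
                    "phenotype": call.phenotype,
                    "group_flag": call.group_flag,
                }
            )
    calls = pd.DataFrame(calls_records)

    with _stage("summarize"):
        summary_rows = []
        for (gname, ri), sub in calls.groupby(["group", "replicate"], sort=True):
            counts = sub["phenotype"].value_counts()
            n = len(sub)
            abnormal = int(sub["group_flag"].eq("abnormal").sum())
            row = {"group": gname, "replicate": ri, "n_total": n,
                   "percent_abnormal": 100.0 * abnormal / n}
            for p in ("ring", "diffuse", "punctate", "invagination", "incomplete"):
                row[f"n_{p}"] = int(counts.get(p, 0))
            summary_rows.append(row)
        summary = pd.DataFrame(summary_rows)

    with _stage("compare"):
        comp_cfg = config.get("comparison", {})
        groups = sorted(config["groups"])
        comparison = pd.DataFrame()
        if len(groups) == 2 and summary["replicate"].nunique() >= 2:
            control_name = next(
                (g for g in groups if config["groups"][g].get("is_control")), groups[0]
            )
            other = [g for g in groups if g != control_name][0]
            a = summary.loc[summary["group"] == other, "percent_abnormal"].to_numpy()
            b = summary.loc[summary["group"] == control_name, "percent_abnormal"].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                res = compare_groups(
                    a, b,
                    test=comp_cfg.get("test", "independent"),
                    direction=comp_cfg.get("direction", "greater"),
                    names=(other, control_name),
                )
                comparison = pd.DataFrame(
                    [{
                        "group_a": other,
                        "group_b": control_name,
                        "mean_a": res.means[0],
                        "mean_b": res.means[1],
                        "sem_a": res.sems[0],
                        "sem_b": res.sems[1],
                        "test": res.test,
                        "direction": res.direction,
                        "t_statistic": res.statistic,
                        "p_value": res.p_value,
                    }]
                )

    with _stage("write"):
        fmt = "%.10g"
        measurements.to_csv(out / "measurements.csv", index=False, float_format=fmt)
        calls.to_csv(out / "calls.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False, float_format=fmt)
        comparison.to_csv(out / "comparison.csv", index=False, float_format=fmt)
        cal_json = {
            str(ri): calibration_to_dict(cal) for ri, cal in sorted(calibrations.items())
        }
        (out / "calibration.json").write_text(json.dumps(cal_json, indent=2) + "\n")
        config_text = json.dumps(config, sort_keys=True)
        log = {
            "package_version": __version__,
            "seed": config["seed"],
            "config": config,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "n_cells": len(rows),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    (out / "INCOMPLETE").unlink()
    return out
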