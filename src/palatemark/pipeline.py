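"""End-to-end experiment orchestration.

``run_experiment`` ties the whole workflow together: obtain casts (from a
manifest CSV or the synthetic generator), split train/validation/test,
preprocess, train both stages, predict on the held-out test split, and
evaluate — writing checkpoints, per-cast predictions, report CSVs and a
run log (config hash + seed) to the output directory.

All randomness flows from one root seed, split into named substreams
(synthetic / split / training) so each component is independently
reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from ._nn import get_state, set_state
from .coarse import CoarseNet, CoarseNetConfig
from .config import PipelineConfig
from .core import LandmarkSet, PalatemarkError
from .evaluation import EvaluationReport, euclidean_errors, summarize
from .geometry import label_angle_template
from .mesh_io import read_mesh, read_pickpoints, write_landmarks_json, write_pickpoints
from .refine import RefineNet, RefineNetConfig
from .synthetic import CastShapeParams, generate_dataset
from .training import (
    PreparedCast,
    predict_prepared,
    prepare_cast,
    split_dataset,
    train_coarse,
    train_refine,
)

__all__ = [
    "derive_seeds",
    "load_manifest",
    "save_network",
    "load_network",
    "run_experiment",
]


def derive_seeds(seed: int) -> dict[str, int]:
    """Named substreams (< 2^31) derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    names = ["synthetic", "split", "training"]
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def load_manifest(path) -> list[tuple]:
    """Read a dataset manifest CSV: cast_id, mesh_path, pp_path [, split]."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mesh = read_mesh(row["mesh_path"])
            mesh.cast_id = row.get("cast_id") or mesh.cast_id
            lms = read_pickpoints(row["pp_path"])
            rows.append((mesh, lms, row.get("split", "")))
    if not rows:
        raise PalatemarkError(f"manifest {path} is empty")
    return rows


def save_network(net, path) -> None:
    """Checkpoint: weights plus embedded config in one ``.npz`` file."""
    kind = "coarse" if isinstance(net, CoarseNet) else "refine"
    meta = json.dumps({"kind": kind, "config": asdict(net.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **get_state(net.params))


def load_network(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    for key in ("sa_radii", "sa_npoints", "sa_nsample", "fp_widths", "mlp_widths"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(tuple(v) if isinstance(v, list) else v for v in cfg[key])
    if "loss_weights" in cfg and isinstance(cfg["loss_weights"], list):
        cfg["loss_weights"] = tuple(cfg["loss_weights"])
    if meta["kind"] == "coarse":
        net = CoarseNet(CoarseNetConfig(**cfg))
    else:
        net = RefineNet(RefineNetConfig(**cfg))
    set_state(net.params, state)
    return net


def run_experiment(
    config: PipelineConfig,
    out_dir,
    manifest=None,
    simulate: int | None = None,
    base_cast_params: CastShapeParams | None = None,
) -> tuple[EvaluationReport, dict]:
    """Split -> preprocess -> train both stages -> predict -> evaluate.

    Returns the refined-prediction report and an extras dict with the
    coarse-only report, training histories and per-cast predictions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)

    if simulate is not None:
        base = base_cast_params or CastShapeParams(
            target_vertices=config.cast_target_vertices
        )
        data = [
            (mesh, lms, "") for mesh, lms in
            generate_dataset(simulate, base, seed=seeds["synthetic"])
        ]
    elif manifest is not None:
        data = load_manifest(manifest)
    else:
        raise PalatemarkError("provide a manifest or a simulate count")

    if any(split for _, _, split in data):
        groups = {"train": [], "val": [], "test": []}
        for mesh, lms, split in data:
            if split not in groups:
                raise PalatemarkError(f"unknown split label {split!r}")
            groups[split].append((mesh, lms))
        train_raw, val_raw, test_raw = groups["train"], groups["val"], groups["test"]
        if not (train_raw and val_raw and test_raw):
            raise PalatemarkError("manifest split has an empty partition")
    else:
        train_raw, val_raw, test_raw = split_dataset(
            [(m, l) for m, l, _ in data],
            config.training.split_fractions,
            seed=seeds["split"],
        )

    n_points = config.preprocess.n_points
    prep = {
        name: [prepare_cast(m, l, n_points) for m, l in part]
        for name, part in (("train", train_raw), ("val", val_raw), ("test", test_raw))
    }

    tconf = replace(config.training, seed=seeds["training"])
    coarse_net, coarse_hist = train_coarse(
        prep["train"], prep["val"], tconf, config.coarse
    )
    refine_net, refine_hist = train_refine(
        prep["train"], prep["val"], tconf, config.refine,
        pipeline=config, coarse_net=coarse_net,
    )
    save_network(coarse_net, out_dir / "coarse_net.npz")
    save_network(refine_net, out_dir / "refine_net.npz")
    pd.DataFrame(coarse_hist).to_csv(out_dir / "coarse_history.csv",
                                     index=False, float_format="%.6f")
    pd.DataFrame(refine_hist).to_csv(out_dir / "refine_history.csv",
                                     index=False, float_format="%.6f")

    # angular template for cluster->FDI assignment, from training ground truth
    template = label_angle_template([c.landmarks_norm for c in prep["train"]])
    template.save(out_dir / "label_angle_template.txt")

    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    errors, coarse_errors = {}, {}
    preds, truths = [], []
    for cast in prep["test"]:
        refined, coarse_only = predict_prepared(
            cast, coarse_net, refine_net, config, label_template=template
        )
        errors[cast.cast_id] = euclidean_errors(refined, cast.landmarks_mm)
        coarse_errors[cast.cast_id] = euclidean_errors(coarse_only, cast.landmarks_mm)
        preds.append(refined)
        truths.append(cast.landmarks_mm)
        write_pickpoints(refined, pred_dir / f"{cast.cast_id}.pp")
        write_landmarks_json(refined, pred_dir / f"{cast.cast_id}.json")

    report = summarize(errors, preds, truths)
    coarse_report = summarize(coarse_errors)
    report.to_csv(out_dir / "report.csv")
    coarse_report.to_csv(out_dir / "coarse_report.csv")
    report.axis_table.to_csv(out_dir / "axis_mae.csv", index=False,
                             float_format="%.6f")

    run_log = {
        "package_version": _version,
        "profile": config.profile,
        "seed": config.seed,
        "substream_seeds": seeds,
        "config_hash": config.config_hash(),
        "n_train": len(prep["train"]),
        "n_val": len(prep["val"]),
        "n_test": len(prep["test"]),
        "overall_mean_error_mm": report.overall_mean,
        "coarse_only_mean_error_mm": coarse_report.overall_mean,
    }
    (out_dir / "run.json").write_text(json.dumps(run_log, indent=1))

    extras = {
        "coarse_report": coarse_report,
        "coarse_history": coarse_hist,
        "refine_history": refine_hist,
        "predictions": preds,
        "truths": truths,
        "errors": errors,
        "coarse_errors": coarse_errors,
        "coarse_net": coarse_net,
        "refine_net": refine_net,
        "prepared": prep,
    }
    return report, extras
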