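"""End-to-end run orchestration: generate -> preprocess -> train ->
evaluate -> compare -> explain, under one config, with per-stage logs and a
run manifest.

Every run directory is self-describing: it holds a config snapshot
sufficient to reproduce the run, per-epoch metrics, the confusion matrix, a
comparison table and saliency output.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baselines, dmcnn, interpret, preprocess, spectra_io, synthgen

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "load_run_config"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class RunConfig:
    """One self-contained experiment description."""

    output_dir: str = "runs/run0"
    seed: int = 0
    synth: "synthgen.SynthConfig | None" = None     # or data_path below
    data_path: "str | None" = None
    manifest_path: "str | None" = None
    preprocess: "preprocess.PreprocessConfig | None" = None
    model: "dmcnn.DMCNNConfig | None" = None
    train: "dmcnn.TrainConfig | None" = None
    comparisons: tuple = ()                          # e.g. ("knn", "rf", "lenet")
    explain_layer: "str | None" = None
    explain_count: int = 4

    def __post_init__(self):
        if self.synth is None and self.data_path is None:
            self.synth = synthgen.default_angelica_like_config(self.seed)
        if self.preprocess is None:
            self.preprocess = preprocess.PreprocessConfig()
        if self.model is None:
            self.model = dmcnn.DMCNNConfig()
        if self.train is None:
            self.train = dmcnn.TrainConfig.scaled_cpu(seed=self.seed)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "synth" in raw and raw["synth"] is not None:
        s = dict(raw["synth"])
        if "lines" in s:
            s["lines"] = tuple(synthgen.LineSpec(**ln) for ln in s["lines"])
        kwargs["synth"] = synthgen.SynthConfig(**s)
    if "preprocess" in raw and raw["preprocess"] is not None:
        p = dict(raw["preprocess"])
        if "stage_order" in p:
            p["stage_order"] = tuple(p["stage_order"])
        kwargs["preprocess"] = preprocess.PreprocessConfig(**p)
    if "model" in raw and raw["model"] is not None:
        m = dict(raw["model"])
        for key in ("kernel_sizes", "mlp_hidden"):
            if key in m:
                m[key] = tuple(m[key])
        kwargs["model"] = dmcnn.DMCNNConfig(**m)
    if "train" in raw and raw["train"] is not None:
        t = dict(raw["train"])
        if "split_ratios" in t:
            t["split_ratios"] = tuple(t["split_ratios"])
        kwargs["train"] = dmcnn.TrainConfig(**t)
    for key in ("output_dir", "seed", "data_path", "manifest_path",
                "comparisons", "explain_layer", "explain_count"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "comparisons" else raw[key]
    return RunConfig(**kwargs)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest (also written
    to ``<output_dir>/manifest.json``).  A stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    manifest: dict = {"artifacts": {}, "metrics": {}}

    def log(stage: str, msg: str):
        line = f"{time.strftime('%Y-%m-%d %H:%M:%S')} [{stage}] {msg}"
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    def stage(name):
        def wrap(fn):
            try:
                log(name, "start")
                result = fn()
                log(name, "done")
                return result
            except Exception as exc:
                log(name, f"FAILED: {exc}")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # config snapshot first: the run directory must be self-describing
    snap = out / "config.yaml"
    with open(snap, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)
    manifest["artifacts"]["config"] = str(snap)

    @stage("generate")
    def ds() -> spectra_io.SpectralDataset:
        if cfg.data_path is not None:
            return spectra_io.read_dataset(cfg.data_path, cfg.manifest_path)
        return synthgen.generate(cfg.synth)

    @stage("preprocess")
    def prepped():
        return preprocess.preprocess_pipeline(ds, cfg.preprocess)

    @stage("train")
    def trained():
        train_set, val_set, test_set = dmcnn.split_dataset(
            prepped, cfg.train.split_ratios, cfg.train.seed,
            cfg.train.group_aware_split)
        model = dmcnn.build_model(cfg.model, seed=cfg.train.seed)
        model, history = dmcnn.train(model, train_set, val_set, cfg.train)
        result = dmcnn.evaluate(model, test_set, history)
        epochs = out / "epochs.csv"
        with open(epochs, "w") as fh:
            fh.write("epoch,train_accuracy,val_accuracy\n")
            for e, (ta, va) in enumerate(zip(history.train_accuracy_trace,
                                             history.val_accuracy_trace), 1):
                fh.write(f"{e},{ta},{va}\n")
        conf = out / "confusion.csv"
        with open(conf, "w") as fh:
            fh.write("tp,tn,fp,fn,accuracy\n")
            fh.write(f"{result.tp},{result.tn},{result.fp},{result.fn},"
                     f"{result.accuracy}\n")
        manifest["artifacts"]["epochs"] = str(epochs)
        manifest["artifacts"]["confusion"] = str(conf)
        manifest["metrics"]["dmcnn_test_accuracy"] = result.accuracy
        return model, test_set, result

    model, test_set, result = trained

    if cfg.comparisons:
        @stage("compare")
        def _compare():
            rows = []
            for name in cfg.comparisons:
                if name in baselines.ML_METHODS:
                    r, cv = baselines.run_ml(prepped, baselines.MLSpec(method=name),
                                             seed=cfg.seed)
                    rows.append((name, r.accuracy, cv))
                elif name in baselines.CLASSIC_CNNS:
                    tr, va, te = dmcnn.split_dataset(
                        prepped, cfg.train.split_ratios, cfg.train.seed)
                    m = baselines.build_classic_cnn(
                        name, prepped.n_points, len(prepped.class_names),
                        seed=cfg.seed)
                    m, _ = dmcnn.train(m, tr, None, cfg.train)
                    rows.append((name, dmcnn.evaluate(m, te).accuracy, float("nan")))
                else:
                    raise ValueError(f"unknown comparison method {name!r}")
            table = out / "comparison.csv"
            with open(table, "w") as fh:
                fh.write("method,test_accuracy,cv_accuracy\n")
                for name, acc, cv in rows:
                    fh.write(f"{name},{acc},{cv}\n")
            manifest["artifacts"]["comparison"] = str(table)
            manifest["metrics"]["comparisons"] = {
                name: acc for name, acc, _ in rows}
        _compare

    @stage("explain")
    def _explain():
        k = min(cfg.explain_count, len(test_set))
        path = out / "saliency.csv"
        with open(path, "w") as fh:
            fh.write("sample_id,wavelength_nm,relevance\n")
            for spec in list(test_set.spectra)[:k]:
                sm = interpret.grad_cam_1d(model, spec,
                                           target_layer=cfg.explain_layer)
                for w, r in zip(sm.wavelengths, sm.relevance):
                    fh.write(f"{spec.sample_id},{w},{r}\n")
        manifest["artifacts"]["saliency"] = str(path)
    _explain

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest
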