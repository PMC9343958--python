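"""End-to-end orchestration: simulate/load -> screen -> filter -> window ->
normalize -> split -> train -> evaluate, with every artifact written under a
self-describing run directory.

Data-level determinism (window counts, split indices, manifests) is exact
under a fixed seed; training reproducibility is statistical, as usual for
stochastic optimisation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as model_mod
from . import preprocess as pre
from . import synth
from .evaluation import confusion, metrics, write_report

logger = logging.getLogger("tasteeg")

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "real"
    manifest: str | None = None  # required in real mode
    out_dir: str = "runs/run"
    seed: int = 0
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    preprocess: pre.PreprocessConfig = field(default_factory=pre.PreprocessConfig)
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    train: model_mod.TrainConfig = field(default_factory=model_mod.TrainConfig)
    split_fraction: float = 0.7
    split_mode: str = "group"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise PipelineError(f"mode must be simulate or real, got {self.mode!r}")
        if self.mode == "real" and not self.manifest:
            raise PipelineError("real mode requires a manifest path")


def _asdict_config(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # class_profiles keys are fine; tuples -> lists for YAML/JSON friendliness
    return json.loads(json.dumps(d, default=list))


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document; top-level keys mirror
    the dataclass fields, nested sections mirror the stage configs."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    synth_kwargs = raw.pop("synth", {}) or {}
    if "class_profiles" in synth_kwargs:
        synth_kwargs["class_profiles"] = {
            cls: tuple(tuple(t) for t in triples)
            for cls, triples in synth_kwargs["class_profiles"].items()
        }
    if "classes" in synth_kwargs:
        synth_kwargs["classes"] = tuple(synth_kwargs["classes"])
    if "envelope" in synth_kwargs:
        synth_kwargs["envelope"] = tuple(synth_kwargs["envelope"])
    pre_kwargs = raw.pop("preprocess", {}) or {}
    model_kwargs = raw.pop("model", {}) or {}
    if "branches" in model_kwargs:
        model_kwargs["branches"] = tuple(
            model_mod.BranchSpec(**b) for b in model_kwargs["branches"]
        )
    if "dense_sizes" in model_kwargs:
        model_kwargs["dense_sizes"] = tuple(model_kwargs["dense_sizes"])
    if "input_shape" in model_kwargs:
        model_kwargs["input_shape"] = tuple(model_kwargs["input_shape"])
    train_kwargs = raw.pop("train", {}) or {}
    return PipelineConfig(
        synth=synth.SynthConfig(**synth_kwargs),
        preprocess=pre.PreprocessConfig(**pre_kwargs),
        model=model_mod.ModelConfig(**model_kwargs),
        train=model_mod.TrainConfig(**train_kwargs),
        **raw,
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report dictionary.

    All artifacts (resolved config, manifest, split indices, training
    history, confusion matrix, metrics) land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_asdict_config(config), indent=2))

    if config.mode == "simulate":
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        rs = _stage("simulate")(synth.generate_dataset)(synth_cfg)
        _stage("simulate")(synth.write_recording_set)(rs, out / "recordings")
    else:
        rs = _stage("load")(synth.read_recording_set)(config.manifest, fs=config.synth.fs)
    logger.info("stage=input recordings=%d classes=%s", len(rs), rs.classes)

    wm, rejected = _stage("preprocess")(pre.preprocess_recordings)(rs, config.preprocess)
    logger.info("stage=screen kept=%d rejected=%d", len(rs) - len(rejected), len(rejected))
    logger.info("stage=window windows=%d window_len=%d", len(wm), wm.windows.shape[1])

    ds = _stage("split")(pre.split)(
        wm, fraction=config.split_fraction, mode=config.split_mode, seed=config.seed
    )
    logger.info("stage=split mode=%s train=%d test=%d", ds.mode, len(ds.train), len(ds.test))
    np.savetxt(out / "train_idx.txt", ds.train_idx, fmt="%d")
    np.savetxt(out / "test_idx.txt", ds.test_idx, fmt="%d")

    net = _stage("train")(model_mod.build_model)(config.model, seed=config.seed)
    tm = _stage("train")(model_mod.train)(net, ds, config.train)
    pd.DataFrame(tm.history).to_csv(out / "history.csv", index=False)

    predicted, _probs = _stage("evaluate")(model_mod.predict)(tm, ds.test)
    cm = _stage("evaluate")(confusion)(ds.test.labels, predicted, tm.class_order)
    report = _stage("evaluate")(metrics)(cm)
    write_report(report, cm, out)

    run_report = {
        "mode": config.mode,
        "seed": config.seed,
        "n_recordings": len(rs),
        "n_rejected": len(rejected),
        "rejected": {rid: list(rep.violations) for rid, rep in rejected},
        "n_windows": len(wm),
        "split": {"mode": ds.mode, "fraction": ds.fraction,
                  "train": len(ds.train), "test": len(ds.test)},
        "final_train_acc": tm.history[-1]["train_acc"] if tm.history else None,
        "test_micro_accuracy": cm.micro_accuracy,
        "macro": report.to_json_dict()["macro"],
    }
    (out / "run_report.json").write_text(json.dumps(run_report, indent=2))
    return run_report


def make_report(run_dir: str | Path) -> str:
    """Render a human-readable summary (per-class metric table plus macro
    averages) from a completed run directory.  Deterministic: identical
    runs give byte-identical reports."""
    run_dir = Path(run_dir)
    missing = [name for name in ("metrics_per_class.csv", "run_report.json",
                                 "confusion_matrix.csv")
               if not (run_dir / name).exists()]
    if missing:
        raise PipelineError(f"incomplete run at {run_dir}: missing {missing}")
    per_class = pd.read_csv(run_dir / "metrics_per_class.csv", index_col=0)
    if per_class.empty:
        raise PipelineError(f"run at {run_dir} evaluated an empty test set")
    run_report = json.loads((run_dir / "run_report.json").read_text())
    lines = [
        "Classification performance",
        "==========================",
        f"{'':12s}{'Accuracy':>10s}{'Precision':>11s}{'Recall':>9s}{'F1 score':>10s}",
    ]
    for cls, row in per_class.iterrows():
        lines.append(
            f"{str(cls).capitalize():12s}{row['accuracy']:>10.4f}"
            f"{row['precision']:>11.4f}{row['recall']:>9.4f}{row['f1']:>10.4f}"
        )
    macro = run_report["macro"]
    lines.append("")
    lines.append(
        f"Macro averages: accuracy {macro['accuracy']:.3f}, "
        f"precision {macro['precision']:.3f}, recall {macro['recall']:.3f}, "
        f"F1 {macro['f1']:.3f}"
    )
    lines.append(f"Windows: {run_report['n_windows']}; "
                 f"split {run_report['split']['mode']} "
                 f"{run_report['split']['train']}/{run_report['split']['test']}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
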