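"""End-to-end orchestration: filter → detect → sequence → cluster →
feature map → train → evaluate, with deterministic seeding and a manifest.

A single global seed fans out to per-stage seeds by hashing the stage name
with the seed (CRC32), so stages are individually reproducible and do not
share RNG streams. Records that fail preprocessing (e.g. fewer than three
detected beats) are skipped and counted, never fatal.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cnn as cnn_mod
from .clustering import (ClusteringParams, build_sequences,
                         select_representative)
from .cnn import CnnConfig
from .evaluation import EvalReport, build_report
from .features import StftParams, build_feature_map
from .io import CLASSES, EcgRecord, read_record
from .preprocess import FilterSpec, bandpass_filter, detect_r_peaks_combined


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2 ** 31)


@dataclass
class PipelineConfig:
    input_dir: str = ""
    output_dir: str = ""
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    stft: StftParams = field(default_factory=StftParams)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    train_fraction: float = 0.8
    test_fraction: float = 0.2
    folds: int = 5
    epochs: int | None = None  # None -> cnn.epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train and test fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in [("filter_spec", FilterSpec),
                         ("clustering", ClusteringParams),
                         ("stft", StftParams)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if isinstance(kwargs.get("cnn"), dict):
            sub = dict(kwargs["cnn"])
            if "conv_groups" in sub:
                sub["conv_groups"] = [
                    cnn_mod.ConvGroupSpec(
                        filters=g["filters"],
                        kernel=tuple(g["kernel"]),
                        stride=tuple(g.get("stride", (1, 1))),
                        pool=tuple(g["pool"]) if g.get("pool") else None,
                        dropout=g.get("dropout", 0.5),
                    ) for g in sub["conv_groups"]]
            kwargs["cnn"] = CnnConfig(**sub)
        return cls(**kwargs)


def load_records(input_dir) -> list[EcgRecord]:
    paths = sorted(p for p in Path(input_dir).iterdir()
                   if p.suffix.lower() in (".csv", ".npy", ".hea"))
    return [read_record(p) for p in paths]


def extract_feature_maps(records, config: PipelineConfig):
    """Per record: filter, detect, window, select representative, map.

    Returns (maps, labels, manifest_entries, skipped).
    """
    maps, labels, entries = [], [], []
    skipped = 0
    base_seed = stage_seed(config.seed, "clustering")
    for k, rec in enumerate(records):
        entry = {"record_id": rec.record_id, "label": rec.label}
        try:
            filt = bandpass_filter(rec, config.filter_spec)
            peaks = detect_r_peaks_combined(filt.signal[0], filt.fs)
            seqs = build_sequences(filt, peaks)
            if not seqs:
                raise ValueError("no usable three-beat window")
            params = ClusteringParams(
                ratio_threshold=config.clustering.ratio_threshold,
                max_recursion=config.clustering.max_recursion,
                n_restarts=config.clustering.n_restarts,
                seed=(base_seed + k) % (2 ** 31),
            )
            rep, trace = select_representative(seqs, params)
            fmap = build_feature_map(rep, config.stft)
            maps.append(fmap)
            labels.append(rec.label)
            entry.update({
                "status": "ok", "n_peaks": len(peaks),
                "n_sequences": len(seqs),
                "representative": [rep.start_sample, rep.end_sample],
                "trace": trace.levels, "selected_index": trace.selected_index,
            })
        except (ValueError, KeyError) as exc:
            skipped += 1
            entry.update({"status": "skipped", "reason": str(exc)})
        entries.append(entry)
    return maps, labels, entries, skipped


def run_pipeline(config: PipelineConfig, records=None) -> EvalReport:
    """Execute the whole workflow and return the evaluation report.

    ``records`` may be passed directly (e.g. synthetic); otherwise they are
    read from ``config.input_dir``. Artifacts (manifest, report) are written
    to ``config.output_dir`` when set.
    """
    if records is None:
        if not config.input_dir:
            raise ValueError("no records given and no input_dir configured")
        records = load_records(config.input_dir)
    if not records:
        raise ValueError("no input records")
    unlabeled = [r.record_id for r in records if not r.has_labels]
    if unlabeled:
        raise ValueError(f"records without labels cannot be trained on: {unlabeled}")

    maps, labels, entries, skipped = extract_feature_maps(records, config)
    if not maps:
        raise ValueError("all records failed preprocessing")

    model = cnn_mod.build_model(config.cnn)
    model = cnn_mod.train(model, maps, labels,
                          split_seed=stage_seed(config.seed, "split"),
                          folds=config.folds, epochs=config.epochs)
    test_idx = model.test_indices
    x_test = [maps[i] for i in test_idx]
    y_test = [labels[i] for i in test_idx]
    proba = cnn_mod.predict_proba(model, x_test)
    pred = [model.class_names[j] for j in proba.argmax(axis=1)]
    classes = model.class_names if config.cnn.n_classes != len(CLASSES) \
        else list(CLASSES)
    report = build_report(y_test, pred, proba, classes=classes)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("clustering", "split")},
            "n_records": len(records), "n_evaluated": len(maps),
            "n_skipped": skipped,
            "filter": asdict(config.filter_spec),
            "stft": asdict(config.stft),
            "records": entries,
            "history": _jsonable(model.history),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report.to_json(out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
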