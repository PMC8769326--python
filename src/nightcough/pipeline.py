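"""End-to-end orchestration: synthesize/ingest -> detect -> features ->
train -> score -> evaluate -> sleep analysis, from one YAML config.

Everything is seeded; rerunning with the same config reproduces the same
artifacts bit-for-bit, and a manifest records the config hash and seeds.
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

from . import detect as det
from . import synth as syn
from .dnn import NetworkModel, TrainingConfig, build_network, train_dnn
from .evaluate import (best_j_threshold, confusion_from_predictions,
                       metrics_from_confusion, roc_pr_curves)
from .features import FEATURE_NAMES, extract_features
from .gmm import GMMClassifier
from .preprocess import Recording, load_audio, preprocess
from .select import resolve_feature_mask
from .sleep import cough_rate_by_stage

log = logging.getLogger("nightcough")

#: Constants frozen at the published operating point.
PAPER_DEFAULTS = {
    "frame_length_s": 0.020,
    "overlap": 0.5,
    "B": 0.08,
    "A": 200.0,
    "min_duration_s": 0.15,
    "max_duration_s": 1.1,
    "part1_window_s": 0.079,
    "voiced_threshold": 0.45,
    "gmm_orders": [1, 1, 16],
    "gmm_threshold": 1.17,
    "dnn_threshold": -2.22,
    "learning_rate": 5e-6,
    "batch_size": 32,
    "epochs": 250,
}

__all__ = ["PipelineConfig", "SubjectData", "split_subjects", "label_events",
           "build_corpus", "run_pipeline", "PAPER_DEFAULTS"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    n_subjects: int = 16
    night_duration: float = 1200.0
    events_per_hour: dict = field(
        default_factory=lambda: {"cough": 70.0, "snore": 325.0, "noise": 325.0})
    split_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    feature_mask: str = "all"          # all | paper
    classifier: str = "dnn"            # gmm | dnn
    detection: dict = field(default_factory=lambda: dict(PAPER_DEFAULTS))
    dnn_learning_rate: float = 1e-3    # see ledger: scaled for small corpora
    dnn_epochs: int = 150

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class SubjectData:
    """Per-subject artifacts of the synthetic corpus."""

    subject_id: str
    events: list
    labels: np.ndarray          # cough | snore | noise per detected event
    features: np.ndarray        # (n_events, 34)
    hypnogram: syn.Hypnogram
    n_planted: dict[str, int]


def split_subjects(cough_counts: dict[str, int],
                   fractions=(0.4, 0.3, 0.3),
                   rng: np.random.Generator | int | None = None
                   ) -> dict[str, list[str]]:
    """Subject-disjoint train/dev/test split, greedily balanced on cough
    counts toward the target fractions."""
    if len(cough_counts) < 3:
        raise ValueError("need at least 3 subjects to split three ways")
    rng = np.random.default_rng(rng)
    names = ["train", "dev", "test"]
    total = sum(cough_counts.values())
    targets = np.asarray(fractions, dtype=float) * total
    subjects = list(cough_counts)
    rng.shuffle(subjects)
    subjects.sort(key=lambda s: -cough_counts[s])
    assigned = {n: [] for n in names}
    sums = np.zeros(3)
    for s in subjects:
        deficit = (targets - sums) / np.maximum(targets, 1e-9)
        i = int(np.argmax(deficit))
        assigned[names[i]].append(s)
        sums[i] += cough_counts[s]
    for n in names:  # every split must be inhabited
        if not assigned[n]:
            donor = max(names, key=lambda m: len(assigned[m]))
            assigned[n].append(assigned[donor].pop())
    return assigned


def label_events(events: list[det.SoundEvent],
                 annotations: list[syn.EventAnnotation]) -> np.ndarray:
    """Ground-truth label per detected event by interval overlap.

    An event takes the label of the annotation it overlaps most;
    unmatched detections (pure background) count as noise.
    """
    labels = []
    for ev in events:
        best, best_ov = "noise", 0.0
        for a in annotations:
            ov = min(ev.end_s, a.offset_s) - max(ev.start_s, a.onset_s)
            if ov > best_ov:
                best, best_ov = a.label, ov
        labels.append(best)
    return np.asarray(labels)


def _process_recording(rec: Recording, cfg_det: dict) -> list[det.SoundEvent]:
    es = det.frame_energy(rec, cfg_det["frame_length_s"], cfg_det["overlap"])
    hist = det.build_histogram(es)
    th = det.compute_thresholds(hist, A=cfg_det["A"], B=cfg_det["B"])
    return det.detect_events(es, th, cfg_det["min_duration_s"],
                             cfg_det["max_duration_s"], recording=rec)


def build_corpus(config: PipelineConfig) -> list[SubjectData]:
    """Generate, detect and featurize one synthetic subject per seed offset.

    The waveform is discarded after feature extraction so memory stays
    flat regardless of corpus size.
    """
    subjects = []
    cfg_det = config.detection
    for i in range(config.n_subjects):
        sid = f"synth{i:03d}"
        scfg = syn.SynthConfig(
            night_duration=config.night_duration,
            events_per_hour=dict(config.events_per_hour),
            rng_seed=config.seed * 10_000 + i)
        night = syn.generate_night(scfg)
        rec = Recording(night.samples, night.sample_rate, subject_id=sid)
        events = _process_recording(rec, cfg_det)
        labels = label_events(events, night.annotations)
        feats = np.array([extract_features(ev).as_array() for ev in events]) \
            if events else np.empty((0, len(FEATURE_NAMES)))
        subjects.append(SubjectData(
            subject_id=sid, events=events, labels=labels, features=feats,
            hypnogram=night.hypnogram,
            n_planted={k: sum(a.label == k for a in night.annotations)
                       for k in ("cough", "snore", "noise")}))
        log.info("subject %s: %d planted events, %d detected",
                 sid, len(night.annotations), len(events))
    return subjects


def _stack(subjects: list[SubjectData], cols: np.ndarray):
    X = np.vstack([s.features for s in subjects if len(s.features)])[:, cols]
    y = np.concatenate([s.labels for s in subjects if len(s.labels)])
    sid = np.concatenate([[s.subject_id] * len(s.labels)
                          for s in subjects if len(s.labels)])
    return X, y, sid


def run_pipeline(config: PipelineConfig,
                 wav_paths: list[str | Path] | None = None) -> dict:
    """Run the full workflow and write artifacts under ``config.out_dir``.

    With ``wav_paths`` given, those recordings are ingested instead of the
    synthetic corpus (no ground-truth labels; scoring-only mode).
    Returns a results dict (also serialized into the manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    names = resolve_feature_mask(config.feature_mask)
    cols = np.asarray([FEATURE_NAMES.index(n) for n in names])

    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    if wav_paths:
        rows = []
        for p in wav_paths:
            rec = preprocess(load_audio(p))
            events = _process_recording(rec, config.detection)
            det.write_events_csv(events, out / f"{rec.subject_id}_events.csv")
            rows.append({"subject": rec.subject_id, "events": len(events)})
        results["ingested"] = rows
        (out / "manifest.json").write_text(json.dumps(results, indent=2))
        return results

    subjects = build_corpus(config)
    if not any(len(s.events) for s in subjects):
        results["note"] = "no events detected; evaluation skipped"
        det.write_events_csv([], out / "events.csv")
        (out / "manifest.json").write_text(json.dumps(results, indent=2))
        return results
    cough_counts = {s.subject_id: int(np.sum(s.labels == "cough"))
                    for s in subjects}
    splits = split_subjects(cough_counts, config.split_fractions, rng)
    by_split = {
        name: [s for s in subjects if s.subject_id in splits[name]]
        for name in ("train", "dev", "test")}
    if any(not v for v in by_split.values()):
        results["note"] = "empty split; evaluation skipped"
        (out / "manifest.json").write_text(json.dumps(results, indent=2))
        return results

    X_tr, y_tr, _ = _stack(by_split["train"], cols)
    X_dev, y_dev, _ = _stack(by_split["dev"], cols)
    X_te, y_te, _ = _stack(by_split["test"], cols)
    results["events"] = {name: int(len(v))
                         for name, v in (("train", y_tr), ("dev", y_dev),
                                         ("test", y_te))}
    if not (np.any(y_tr == "cough") and np.any(y_te == "cough")):
        results["note"] = "no coughs detected; evaluation skipped"
        (out / "manifest.json").write_text(json.dumps(results, indent=2))
        return results

    # GMM branch
    gmm = GMMClassifier.fit(X_tr, y_tr,
                            orders=tuple(config.detection["gmm_orders"]),
                            rng=config.seed)
    gmm_th, _ = best_j_threshold(gmm.llr(X_dev), y_dev == "cough")
    gmm.threshold = gmm_th
    gmm.save(out / "gmm_model.json")

    # DNN branch
    spec = build_network(len(cols))
    tcfg = TrainingConfig(learning_rate=config.dnn_learning_rate,
                          batch_size=config.detection["batch_size"],
                          epochs=config.dnn_epochs, rng_seed=config.seed)
    dnn = train_dnn(spec, X_tr, y_tr, tcfg)
    dnn_th, _ = best_j_threshold(dnn.llr(X_dev), y_dev == "cough")
    dnn.threshold = dnn_th
    dnn.save(out / "dnn_model.json")

    for name, model in (("gmm", gmm), ("dnn", dnn)):
        scores = model.llr(X_te)
        truth = y_te == "cough"
        cm = confusion_from_predictions(scores > model.threshold, truth)
        rep = metrics_from_confusion(cm)
        curves = roc_pr_curves(scores, truth)
        results[name] = {
            "threshold": float(model.threshold),
            "sensitivity": rep.sensitivity, "ppv": rep.ppv,
            "specificity": rep.specificity, "accuracy": rep.accuracy,
            "kappa": rep.kappa,
            "roc_auc": curves["roc_auc"], "pr_auc": curves["pr_auc"],
        }
        log.info("%s test: sens=%.3f ppv=%.3f", name,
                 rep.sensitivity or -1, rep.ppv or -1)

    # sleep analysis on detected test-split coughs (best classifier)
    rate_frames = []
    best = dnn if config.classifier == "dnn" else gmm
    for s in by_split["test"]:
        if not len(s.features):
            continue
        mask = best.llr(s.features[:, cols]) > best.threshold
        coughs = [ev for ev, m in zip(s.events, mask) if m]
        table = cough_rate_by_stage(coughs, s.hypnogram)
        df = table.to_frame()
        df.insert(0, "subject", s.subject_id)
        rate_frames.append(df)
    if rate_frames:
        pd.concat(rate_frames).to_csv(out / "cough_rates.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(results, indent=2))
    return results
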