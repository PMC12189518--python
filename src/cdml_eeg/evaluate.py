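"""Per-subject 10-fold cross-validation, ablations, and report aggregation.

Each subject's trials are split into ten stratified disjoint folds. For every
fold a fresh head is trained on the other nine tenths — with a further 10%
stratified inner split held out for minimum-validation-loss model selection,
so the test fold never influences training — and accuracy is measured on the
held-out tenth. A subject's score is the mean over folds; the headline number
is the unweighted mean over subjects.

The frozen backbone is identical across folds (same seed, never updated), so
its features for each tensor are computed once per subject and shared by all
folds; the per-fold model remains fresh where it can differ (the head).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import (BackboneSpec, DataError, HeadSpec, TrainedModel,
                         build_model, train_head_on_features)
from .config import PipelineConfig, TrainConfig
from .eeg_io import extract_trials, read_recording
from .representation import CDMLTensor, build_dataset
from .synthetic import SyntheticSpec, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["CVReport", "crossvalidate", "run_experiment"]


@dataclass
class CVReport:
    """Fold-level accuracies per subject plus their aggregates."""

    per_subject: dict[str, list[float]]
    fingerprint: str = ""
    seed: int = 0

    @property
    def per_subject_mean(self) -> dict[str, float]:
        return {s: float(np.mean(a)) for s, a in self.per_subject.items()}

    @property
    def grand_mean(self) -> float:
        """Unweighted mean of per-subject means."""
        return float(np.mean(list(self.per_subject_mean.values())))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"per_subject": self.per_subject,
                   "per_subject_mean": self.per_subject_mean,
                   "grand_mean": self.grand_mean,
                   "fingerprint": self.fingerprint, "seed": self.seed}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject", "fold", "accuracy"])
            for subject, accs in self.per_subject.items():
                for k, acc in enumerate(accs):
                    w.writerow([subject, k, f"{acc:.6f}"])


def crossvalidate(tensors: list[CDMLTensor], cfg: TrainConfig | None = None,
                  k: int = 10, backbone: BackboneSpec | None = None,
                  head: HeadSpec | None = None,
                  model: TrainedModel | None = None,
                  features: np.ndarray | None = None) -> list[float]:
    """Stratified k-fold accuracies for one subject's tensors.

    Folds are disjoint, cover every sample, and are deterministic given
    ``cfg.seed``. Pass ``model`` to reuse an already-built frozen backbone,
    and ``features`` to reuse its (label-independent) trunk output for these
    tensors, e.g. across permutation-null repetitions.
    """
    cfg = cfg or TrainConfig()
    if len(tensors) < k:
        raise DataError(f"need at least {k} samples for {k} folds, got {len(tensors)}")
    labels = np.array([t.label for t in tensors])
    if len(set(labels)) < 2:
        raise DataError("both classes must be present")

    if model is None:
        model = build_model(backbone or BackboneSpec(), head or HeadSpec(),
                            seed=cfg.seed)
    feats = model.features(tensors) if features is None else features
    if len(feats) != len(tensors):
        raise ValueError("features/tensors length mismatch")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    accuracies = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(feats, labels)):
        tr_idx, val_idx = train_test_split(
            train_idx, test_size=cfg.val_fraction, stratify=labels[train_idx],
            random_state=cfg.seed + fold)
        fold_model = TrainedModel(
            backbone=model.backbone, backbone_spec=model.backbone_spec,
            head_spec=model.head_spec,
            head=_fresh_head(model, cfg.seed + fold), seed=cfg.seed + fold)
        fold_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                               epochs=cfg.epochs, batch_size=cfg.batch_size,
                               val_fraction=cfg.val_fraction,
                               seed=cfg.seed + fold)
        train_head_on_features(fold_model, feats[tr_idx], list(labels[tr_idx]),
                               feats[val_idx], list(labels[val_idx]), fold_cfg)
        p = fold_model.head_forward(feats[test_idx])
        pred = np.where(p[:, 1] > p[:, 0], "right", "left")
        accuracies.append(float(np.mean(pred == labels[test_idx])))
    return accuracies


def _fresh_head(model: TrainedModel, seed: int) -> dict[str, np.ndarray]:
    from .classifier import _init_head

    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    return _init_head(model.head["w1"].shape[0], model.head_spec, rng)


def subject_tensors(cfg: PipelineConfig, subject_index: int) -> list[CDMLTensor]:
    """Tensors for one subject, simulated or read from ``cfg.data_dir``."""
    if cfg.data_dir is None:
        subject_id = f"S{subject_index + 1:02d}"
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, cfg.synthetic.seed, subject_index]))
        rec = simulate_session(cfg.synthetic, subject_id=subject_id, rng=rng)
    else:
        files = sorted(p for p in Path(cfg.data_dir).iterdir()
                       if p.suffix.lower() in (".gdf", ".edf"))
        if not files:
            raise IOError(f"no GDF/EDF recordings under {cfg.data_dir}")
        if subject_index >= len(files):
            raise IOError(f"subject index {subject_index} out of range "
                          f"({len(files)} recordings found)")
        rec = read_recording(files[subject_index])
    segments = extract_trials(rec, cfg.window_seconds)
    return build_dataset(segments, cfg)


def run_experiment(cfg: PipelineConfig | None = None) -> CVReport:
    """Full pipeline for every subject: io -> preprocess -> tfr -> stack -> CV."""
    cfg = cfg or PipelineConfig()
    backbone = BackboneSpec(name=cfg.backbone, pretrained=cfg.pretrained,
                            weights_path=cfg.weights_path,
                            input_norm="canonical" if cfg.pretrained else "identity")
    model = build_model(backbone, HeadSpec(), seed=cfg.train.seed)
    report = CVReport(per_subject={}, fingerprint=cfg.fingerprint(),
                      seed=cfg.seed)
    for si in range(cfg.n_subjects):
        tensors = subject_tensors(cfg, si)
        subject_id = tensors[0].subject_id if tensors else f"S{si + 1:02d}"
        accs = crossvalidate(tensors, cfg.train, k=cfg.k_folds, model=model)
        report.per_subject[subject_id] = accs
        logger.info("subject %s: mean fold accuracy %.3f", subject_id,
                    float(np.mean(accs)))
    logger.info("grand mean accuracy: %.4f", report.grand_mean)
    return report
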