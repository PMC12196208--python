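"""End-to-end pipeline: recordings -> frames -> image stacks -> fusion CNN.

Also hosts the two synthetic study drivers used for validation:

* :func:`run_recovery_study` — can the full pipeline recover a planted
  class difference (AD-like slowing vs controls) from held-out subjects,
  and does it stay at chance when the planted effect is zero?
* :func:`run_channel_importance_study` — does single-channel probing
  assign maximal importance to the frontal electrodes when the planted
  class-F signature is frontal-only?

Both studies are deliberately desk-scale: compact cohorts, a few frames
per subject, narrow conv stacks and short schedules, so a full run fits in
minutes on one CPU while exercising every pipeline stage end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import evaluation, modeling
from .core import EEGRecording, MONTAGE_19, preprocess, segment_frames
from .evaluation import (ChannelImportance, kfold_subject_split,
                         normalize_importance, per_class_recall, subject_vote)
from .modeling import CNN1Spec, CNN2Spec, TrainConfig, build_cnn1, build_cnn2
from .synthetic import SyntheticSpec, generate_cohort
from .timefreq import CWTConfig, HilbertConfig, STFTConfig, build_stack

MODALITIES = ("spectrogram", "scalogram", "hilbert")


def stacks_for_recording(rec: EEGRecording, frame_length_s: float = 4.0,
                         overlap_frac: float = 0.5, max_frames: int | None = None,
                         size: int = 128, stft_cfg: STFTConfig | None = None,
                         cwt_cfg: CWTConfig | None = None,
                         hilbert_cfg: HilbertConfig | None = None):
    """Segment a recording and compute the per-frame image stacks."""
    frames = segment_frames(rec, frame_length_s, overlap_frac)
    out = []
    for idx, frame in zip(frames.frame_index, frames.frames):
        if max_frames is not None and idx >= max_frames:
            break
        out.append(build_stack(frame, fs=rec.fs, stft_cfg=stft_cfg,
                               cwt_cfg=cwt_cfg, hilbert_cfg=hilbert_cfg,
                               subject_id=rec.subject_id, frame_index=idx,
                               label=rec.label, size=size))
    return out


@dataclass
class FrameDataset:
    """Flat arrays over all frames of a cohort, one array per modality."""

    spectrogram: np.ndarray  # (N, size, size, 19) float32
    scalogram: np.ndarray
    hilbert: np.ndarray
    y: np.ndarray            # int class indices
    subject_ids: np.ndarray  # str per frame
    classes: tuple

    def __len__(self):
        return len(self.y)

    def modality(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def subset(self, mask) -> "FrameDataset":
        mask = np.asarray(mask)
        return FrameDataset(self.spectrogram[mask], self.scalogram[mask],
                            self.hilbert[mask], self.y[mask],
                            self.subject_ids[mask], self.classes)

    def subjects(self):
        seen = {}
        for sid, yi in zip(self.subject_ids, self.y):
            seen.setdefault(sid, self.classes[yi])
        return list(seen.keys()), [seen[s] for s in seen]

    def single_channel(self, channel: str) -> np.ndarray:
        """(N, size, size, 3) array: the three modalities of one channel."""
        ci = MONTAGE_19.index(channel)
        return np.stack([self.spectrogram[..., ci], self.scalogram[..., ci],
                         self.hilbert[..., ci]], axis=-1)


def build_frame_dataset(cohort, classes, frames_per_subject: int | None = None,
                        size: int = 128, apply_preprocess: bool = False,
                        **tfr_kwargs) -> FrameDataset:
    """Compute stacks for every recording and flatten them into arrays."""
    classes = tuple(classes)
    spec, scal, hil, y, sids = [], [], [], [], []
    for rec in cohort:
        if apply_preprocess:
            rec = preprocess(rec)
        for st in stacks_for_recording(rec, max_frames=frames_per_subject,
                                       size=size, **tfr_kwargs):
            spec.append(st.spectrogram.astype(np.float32))
            scal.append(st.scalogram.astype(np.float32))
            hil.append(st.hilbert.astype(np.float32))
            y.append(classes.index(rec.label))
            sids.append(rec.subject_id)
    return FrameDataset(np.stack(spec), np.stack(scal), np.stack(hil),
                        np.asarray(y), np.asarray(sids), classes)


@dataclass
class PipelineConfig:
    """Architecture and training settings of the three-extractor fusion model."""

    cnn1: CNN1Spec = field(default_factory=CNN1Spec)
    cnn2: CNN2Spec = field(default_factory=CNN2Spec)
    train_cnn1: TrainConfig = field(default_factory=TrainConfig)
    train_cnn2: TrainConfig = field(default_factory=TrainConfig)
    inner_val_fraction: float = 0.2
    seed: int = 0


def small_pipeline_config(seed: int = 0, epochs: int = 15,
                          conv_filters=(8, 16, 32, 64),
                          input_pool: int = 2, batch_size: int = 16) -> PipelineConfig:
    """Desk-scale profile: coarsened input, narrow conv stacks, small batches.

    The 2x2 input pooling and 8/16/32/64 filter widths trade capacity for
    speed so a full cross-validated study runs in minutes on one CPU; the
    small batch size keeps the gradient-step count high enough for the
    batch-norm running statistics to settle on compact cohorts.
    """
    t1 = TrainConfig(max_epochs=epochs, early_stop_patience=epochs,
                     plateau_patience=max(3, epochs // 2), augment=False,
                     batch_size=batch_size, seed=seed)
    t2 = TrainConfig(max_epochs=max(30, 2 * epochs), early_stop_patience=15,
                     plateau_patience=8, augment=False,
                     batch_size=batch_size, seed=seed + 1)
    return PipelineConfig(cnn1=CNN1Spec(conv_filters=conv_filters,
                                        input_pool=input_pool),
                          cnn2=CNN2Spec(), train_cnn1=t1, train_cnn2=t2, seed=seed)


class FusionPipeline:
    """Three frozen per-modality extractors plus the fusion classifier.

    Extractors are trained as standalone classifiers first, then frozen;
    the fusion CNN is trained on their 3x50 feature images. Validation for
    plateau scheduling / early stopping uses a subject-disjoint inner split.
    """

    def __init__(self, config: PipelineConfig | None = None, n_classes: int = 2):
        self.config = config or PipelineConfig()
        self.n_classes = n_classes
        self.cnn1 = {}
        self.cnn2 = None
        self.history = {}

    def _inner_split(self, data: FrameDataset, rng):
        sids, labels = data.subjects()
        sids = np.asarray(sids)
        labels = np.asarray(labels)
        val_sids = []
        for cls in np.unique(labels):
            cls_sids = sids[labels == cls]
            n_val = max(1, int(round(self.config.inner_val_fraction * len(cls_sids))))
            val_sids.extend(rng.choice(cls_sids, size=n_val, replace=False))
        val_mask = np.isin(data.subject_ids, val_sids)
        return data.subset(~val_mask), data.subset(val_mask)

    def fit(self, data: FrameDataset, verbose: bool = False):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        train, val = self._inner_split(data, rng)
        for mi, mod in enumerate(MODALITIES):
            spec1 = replace(cfg.cnn1, in_channels=train.modality(mod).shape[-1],
                            input_hw=train.modality(mod).shape[1:3])
            model = build_cnn1(spec1, n_classes=self.n_classes,
                               seed=cfg.seed * 31 + mi)
            tcfg = replace(cfg.train_cnn1, seed=cfg.train_cnn1.seed * 7 + mi)
            self.history[mod] = modeling.train(
                model, train.modality(mod), train.y, tcfg,
                x_val=val.modality(mod), y_val=val.y, verbose=verbose)
            self.cnn1[mod] = model

        f_train = self._features(train)
        f_val = self._features(val)
        self.cnn2 = build_cnn2(cfg.cnn2, n_classes=self.n_classes,
                               seed=cfg.seed * 31 + 17)
        self.history["fusion"] = modeling.train(
            self.cnn2, f_train, train.y, cfg.train_cnn2,
            x_val=f_val, y_val=val.y, verbose=verbose)
        return self

    def _features(self, data: FrameDataset) -> np.ndarray:
        feats = [self.cnn1[mod].features(data.modality(mod)) for mod in MODALITIES]
        return np.stack(feats, axis=1)[..., None].astype(np.float32)

    def feature_triples(self, data: FrameDataset):
        return modeling.extract_features(
            [self.cnn1[m] for m in MODALITIES],
            [data.modality(m) for m in MODALITIES])

    def predict(self, data: FrameDataset):
        """Frame-level predictions: (class indices, probabilities)."""
        if self.cnn2 is None:
            raise RuntimeError("pipeline is not trained; call fit() first")
        probs = self.cnn2.predict_proba(self._features(data))
        return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# synthetic studies

@dataclass
class StudyConfig:
    """Problem sizes of the desk-scale synthetic studies."""

    n_subjects_per_class: int = 8
    frames_per_subject: int = 10
    duration_s: float = 30.0
    effect_size: float = 1.0
    n_folds: int = 4
    epochs: int = 12
    conv_filters: tuple = (8, 16, 32, 64)
    classes: tuple = ("A", "C")
    seed: int = 0


def recovery_study_config(seed: int = 0) -> StudyConfig:
    """Canonical conditions of the planted-effect recovery study."""
    return StudyConfig(seed=seed)


def null_study_config(seed: int = 0) -> StudyConfig:
    """Null-effect control: same machinery, zero planted effect, smaller cohort."""
    return StudyConfig(effect_size=0.0, n_subjects_per_class=6,
                       frames_per_subject=8, duration_s=20.0, epochs=5,
                       n_folds=3, seed=seed)


def channel_study_config(seed: int = 0) -> StudyConfig:
    """Conditions of the frontal-signature channel-importance study."""
    return StudyConfig(classes=("F", "C"), n_subjects_per_class=5,
                       frames_per_subject=8, duration_s=24.0, seed=seed)


def run_recovery_study(cfg: StudyConfig | None = None, verbose: bool = False):
    """Train/evaluate the fusion pipeline on a synthetic two-class cohort.

    Subject-stratified k-fold CV over subjects: every subject is scored
    exactly once by a model that never saw any of their frames. Returns
    frame- and subject-level metrics plus per-fold validation losses of the
    single-modality extractors and the fusion stage.
    """
    cfg = cfg or StudyConfig()
    spec = SyntheticSpec(n_subjects_per_class=cfg.n_subjects_per_class,
                         classes=cfg.classes, duration_s=cfg.duration_s,
                         effect_size=cfg.effect_size, seed=cfg.seed)
    cohort = generate_cohort(spec)
    data = build_frame_dataset(cohort, cfg.classes,
                               frames_per_subject=cfg.frames_per_subject)

    sids, slabels = data.subjects()
    folds = kfold_subject_split(sids, slabels, k=cfg.n_folds, seed=cfg.seed)

    classes = cfg.classes
    frame_cm = np.zeros((len(classes), len(classes)), dtype=int)
    subj_true, subj_pred = [], []
    fold_val_losses = []
    for fi, (train_ids, test_ids) in enumerate(folds):
        test_mask = np.isin(data.subject_ids, test_ids)
        pipe = FusionPipeline(
            small_pipeline_config(seed=cfg.seed * 101 + fi, epochs=cfg.epochs,
                                  conv_filters=cfg.conv_filters),
            n_classes=len(classes))
        pipe.fit(data.subset(~test_mask), verbose=verbose)
        test = data.subset(test_mask)
        pred, probs = pipe.predict(test)
        frame_cm += evaluation.confusion_matrix(test.y.tolist(), pred.tolist(),
                                                list(range(len(classes))))
        fold_val_losses.append({
            mod: min(pipe.history[mod]["val_loss"]) for mod in MODALITIES
        } | {"fusion": min(pipe.history["fusion"]["val_loss"])})
        for sid in test_ids:
            smask = test.subject_ids == sid
            voted = subject_vote(pred[smask].tolist(), positive_class=0,
                                 threshold=0.5,
                                 frame_probabilities=probs[smask])
            subj_true.append(int(test.y[smask][0]))
            subj_pred.append(int(voted))

    subject_cm = evaluation.confusion_matrix(subj_true, subj_pred,
                                             list(range(len(classes))))
    frame_report = evaluation.compute_metrics(frame_cm, classes,
                                              positive_class=classes[0],
                                              level="frame")
    subject_report = evaluation.compute_metrics(subject_cm, classes,
                                                positive_class=classes[0],
                                                level="subject")
    return {"frame": frame_report, "subject": subject_report,
            "fold_val_losses": fold_val_losses,
            "n_subjects": len(subj_true), "config": cfg}


def run_channel_importance_study(cfg: StudyConfig | None = None,
                                 probe_filters=(8, 16), probe_epochs: int = 8,
                                 n_folds: int = 5, verbose: bool = False):
    """Single-channel probing on a cohort with a frontal class-F signature.

    For each of the 19 electrodes, a compact probe CNN is trained on that
    channel's three-modality 128x128x3 image across shared stratified
    folds; per-class sensitivity (recall) is averaged over folds and
    min-max normalised across channels.
    """
    cfg = cfg or StudyConfig(classes=("F", "C"), n_subjects_per_class=5,
                             frames_per_subject=10, n_folds=5)
    spec = SyntheticSpec(n_subjects_per_class=cfg.n_subjects_per_class,
                         classes=cfg.classes, duration_s=cfg.duration_s,
                         effect_size=cfg.effect_size, seed=cfg.seed)
    cohort = generate_cohort(spec)
    data = build_frame_dataset(cohort, cfg.classes,
                               frames_per_subject=cfg.frames_per_subject)
    sids, slabels = data.subjects()
    folds = kfold_subject_split(sids, slabels, k=n_folds, seed=cfg.seed)

    n_cls = len(cfg.classes)
    sens = np.zeros((n_cls, len(MONTAGE_19)))
    for ci, channel in enumerate(MONTAGE_19):
        x_all = data.single_channel(channel)
        recalls = []
        for fi, (train_ids, test_ids) in enumerate(folds):
            test_mask = np.isin(data.subject_ids, test_ids)
            spec1 = CNN1Spec(in_channels=3, conv_filters=probe_filters,
                             input_hw=x_all.shape[1:3], input_pool=4)
            model = build_cnn1(spec1, n_classes=n_cls,
                               seed=cfg.seed * 97 + fi)  # same per-fold seed across channels
            tcfg = TrainConfig(max_epochs=probe_epochs,
                               early_stop_patience=probe_epochs,
                               plateau_patience=max(2, probe_epochs // 2),
                               augment=False, batch_size=8,
                               seed=cfg.seed * 11 + fi)
            # scheduling validation comes from a random split of the training
            # frames; the held-out fold is never seen before scoring
            modeling.train(model, x_all[~test_mask], data.y[~test_mask], tcfg,
                           verbose=verbose)
            probs = model.predict_proba(x_all[test_mask])
            cm = evaluation.confusion_matrix(data.y[test_mask].tolist(),
                                             probs.argmax(axis=1).tolist(),
                                             list(range(n_cls)))
            recalls.append(per_class_recall(cm))
        sens[:, ci] = np.nanmean(np.stack(recalls), axis=0)
    return normalize_importance(sens, channels=MONTAGE_19, classes=cfg.classes)
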