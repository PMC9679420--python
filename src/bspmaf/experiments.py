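"""End-to-end experiments on synthetic cohorts, at desk scale.

The full pipeline — cohort simulation, Wilson referencing, baseline-wander
injection, 1-40 Hz band-pass, 2-s segmentation with minority-class overlap
augmentation, isopotential rendering, resizing, training and evaluation —
wired together for the two study designs (intra-patient 7:2:1 split and
inter-patient five-fold cross-validation).

Default problem sizes are deliberately small so a complete inter-patient
cross-validation runs on one CPU core in minutes: 14 patients (4 recurrent)
at 24 s each, sequences resized to 16 x 16 x 32, and a narrow network
(base width 4).  These are scaled-down analogues of the clinical study
design, not reproductions of its results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    MetricsReport,
    TrainConfig,
    confusion_metrics,
    inter_patient_folds,
    intra_patient_split,
    plan_from_patient_folds,
    roc_auc,
    train_model,
)
from .isopotential import InterpolationGrid, build_sequence, resize_sequence
from .model.network import NetworkConfig, build_network, predict
from .preprocess import (
    NoiseSpec,
    add_baseline_wander,
    apply_wct_reference,
    bandpass_filter,
    build_segment_dataset,
    normalize_amplitude,
)
from .synthetic import (
    LABEL_RECURRENCE,
    CohortSpec,
    ElectrodeLayout,
    generate_cohort,
    generate_electrode_layout,
)


def scaled_cohort_spec(seed: int = 0) -> CohortSpec:
    """The desk-scale study conditions: 14 patients, 4 recurrent, 24 s each."""
    return CohortSpec(n_patients=14, recurrence_fraction=4.0 / 14.0,
                      duration_s=24.0, seed=seed)


def scaled_network_config(hwt: tuple[int, int, int] = (16, 16, 32)) -> NetworkConfig:
    """Narrow network for the scaled-down experiments (channel schedule 4-8-16-32)."""
    return NetworkConfig(input_hwt=hwt, base_channels=4)


@dataclass
class SequenceDataset:
    """Rendered cohort: (N, H, W, T) sequences with labels and provenance."""

    sequences: np.ndarray
    labels: np.ndarray  # 1 = recurrence
    patient_ids: list[str]

    def __len__(self) -> int:
        return len(self.sequences)


def prepare_cohort_sequences(
    spec: CohortSpec,
    layout: ElectrodeLayout | None = None,
    grid_size: int = 64,
    out_hwt: tuple[int, int, int] = (16, 16, 32),
    noise_snr_db: float | None = 12.0,
    segment_seconds: float = 2.0,
    shift_samples: int = 175,
) -> SequenceDataset:
    """Simulate, preprocess and render a cohort into classifier-ready stacks.

    Steps: simulate -> add baseline wander at ``noise_snr_db`` (skipped when
    None) -> WCT reference -> 1-40 Hz band-pass -> segment (overlap-augment
    the recurrence class toward balance) -> per-segment min-max normalize ->
    IDW-render anterior frames at ``grid_size`` -> resize to ``out_hwt``.
    """
    if layout is None:
        layout = generate_electrode_layout()
    recordings = generate_cohort(spec, layout)
    processed = []
    for i, rec in enumerate(recordings):
        if noise_snr_db is not None:
            rec = add_baseline_wander(rec, NoiseSpec(snr_db=noise_snr_db, seed=spec.seed + 7919 * i))
        rec = apply_wct_reference(rec, layout)
        rec = bandpass_filter(rec)
        processed.append(rec)
    segments = build_segment_dataset(processed, seconds=segment_seconds,
                                     shift_samples=shift_samples)
    grid = InterpolationGrid.from_layout(layout, size=grid_size)
    h, w, t = out_hwt
    stacks, labels, pids = [], [], []
    for seg in segments:
        seq = build_sequence(normalize_amplitude(seg), grid)
        seq = resize_sequence(seq, width=w, height=h, t_frames=t)
        stacks.append(seq.frames)
        labels.append(1 if seg.label == LABEL_RECURRENCE else 0)
        pids.append(seg.patient_id)
    return SequenceDataset(
        sequences=np.stack(stacks), labels=np.asarray(labels, int), patient_ids=pids
    )


@dataclass
class ExperimentResult:
    metrics: MetricsReport
    history_val_acc: list[float] = field(default_factory=list)


def run_intra_patient_experiment(
    data: SequenceDataset,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Random 7:2:1 segment split, train, report test metrics."""
    net_cfg = net_cfg or scaled_network_config(data.sequences.shape[1:4])
    train_cfg = train_cfg or TrainConfig(epochs=12, seed=seed)
    plan = intra_patient_split(len(data), seed=seed)
    model = build_network(net_cfg, seed=seed)
    model, hist = train_model(
        model,
        data.sequences[plan.train_idx], data.labels[plan.train_idx],
        data.sequences[plan.val_idx], data.labels[plan.val_idx],
        train_cfg,
    )
    scores = predict(model, data.sequences[plan.test_idx])[:, 1]
    rep = confusion_metrics(scores, data.labels[plan.test_idx])
    try:
        rep.AUC = roc_auc(scores, data.labels[plan.test_idx])
    except Exception:
        pass
    return ExperimentResult(metrics=rep, history_val_acc=hist.val_acc)


@dataclass
class CrossValidationResult:
    fold_metrics: list[MetricsReport]
    mean_acc: float
    mean_auc: float


def run_inter_patient_experiment(
    data: SequenceDataset,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """Patient-grouped five-fold cross-validation.

    Mean ACC averages all folds; mean AUC averages the folds where both
    classes appear in the test partition (a fold whose test patients are all
    non-recurrent has no defined AUC).
    """
    net_cfg = net_cfg or scaled_network_config(data.sequences.shape[1:4])
    train_cfg = train_cfg or TrainConfig(epochs=12, seed=seed)
    patients = sorted(set(data.patient_ids))
    pat_label = {p: int(np.max(data.labels[np.asarray(data.patient_ids) == p])) for p in patients}
    folds = inter_patient_folds(patients, [bool(pat_label[p]) for p in patients],
                                n_folds=n_folds, seed=seed)
    reports, aucs = [], []
    for k, fold in enumerate(folds):
        plan = plan_from_patient_folds(data.patient_ids, fold, seed=seed + k)
        model = build_network(net_cfg, seed=seed + k)
        model, _ = train_model(
            model,
            data.sequences[plan.train_idx], data.labels[plan.train_idx],
            data.sequences[plan.val_idx], data.labels[plan.val_idx],
            train_cfg,
        )
        scores = predict(model, data.sequences[plan.test_idx])[:, 1]
        y = data.labels[plan.test_idx]
        rep = confusion_metrics(scores, y)
        if len(np.unique(y)) == 2:
            rep.AUC = roc_auc(scores, y)
            aucs.append(rep.AUC)
        reports.append(rep)
    mean_acc = float(np.nanmean([r.ACC for r in reports]))
    mean_auc = float(np.mean(aucs)) if aucs else float("nan")
    return CrossValidationResult(fold_metrics=reports, mean_acc=mean_acc, mean_auc=mean_auc)
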