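"""Dataset bookkeeping, intra-/inter-patient splitting, training and metrics.

Two evaluation regimes are supported:

* intra-patient — all segments pooled, shuffled and split 7:2:1 into
  train/validation/test (segments of one patient may appear on both sides);
* inter-patient — patients, not segments, are partitioned into five folds;
  a fold's test patients never contribute training segments, and the scarce
  recurrence-positive patients are spread across folds as evenly as
  possible so every training partition keeps at least one of them.

Classifier quality is reported as sensitivity, specificity, positive
predictive value and accuracy (percent) from the confusion counts, plus the
rank-based (Mann-Whitney) area under the ROC curve.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    ShapeError,
    UndefinedMetricError,
)
from .model.autodiff import Tensor
from .model.layers import Adam
from .model.network import RecurrenceNet3D, sequences_to_batch


# ---------------------------------------------------------------------------
# Subject table
# ---------------------------------------------------------------------------

def load_subject_table(path=None) -> pd.DataFrame:
    """Load a subject inventory CSV (columns: id, recurrence, segments, ...).

    Without a path, returns the bundled example inventory of a 14-patient
    persistent-AF cohort (4 recurrent) whose per-patient segment counts sum
    to 359 recurrent and 813 non-recurrent segments.
    """
    if path is None:
        ref = importlib.resources.files("bspmaf").joinpath("data/subjects.csv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if table["id"].duplicated().any():
        raise InvalidParameterError("duplicate subject ids")
    if (table["segments"] < 0).any():
        raise InvalidParameterError("negative segment count")
    return table


def count_segments_by_outcome(table: pd.DataFrame) -> tuple[int, int]:
    """Sum the segments column by recurrence flag -> (non_recurrent, recurrent)."""
    if len(table) == 0:
        return (0, 0)
    flags = table["recurrence"].astype(str).str.lower().isin(["yes", "true", "1"])
    rec = int(table.loc[flags, "segments"].sum())
    non = int(table.loc[~flags, "segments"].sum())
    return non, rec


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Index-level assignment of segments to partitions."""

    mode: str  # "intra" | "inter"
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    test_patients: tuple[str, ...] = ()
    train_patients: tuple[str, ...] = ()


def intra_patient_split(
    n_segments: int, ratios: tuple[int, int, int] = (7, 2, 1), seed: int = 0
) -> SplitPlan:
    """Uniform shuffle, partition sizes by largest-remainder rounding."""
    if any(r <= 0 for r in ratios):
        raise InvalidParameterError("ratios must be positive")
    if n_segments < 10:
        raise InvalidParameterError("need at least 10 segments")
    total = sum(ratios)
    exact = [n_segments * r / total for r in ratios]
    sizes = [math.floor(e) for e in exact]
    rema = sorted(range(3), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in range(n_segments - sum(sizes)):
        sizes[rema[i % 3]] += 1
    perm = np.random.default_rng(seed).permutation(n_segments)
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitPlan("intra", perm[:a], perm[a:b], perm[b:], seed)


def inter_patient_folds(
    patient_ids: list[str],
    patient_labels: list[bool] | np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Partition patients into folds -> list of (train_patients, test_patients).

    Recurrence-positive patients are dealt round-robin across folds first so
    no fold's test set concentrates them; fold sizes differ by at most one.
    """
    ids = list(map(str, patient_ids))
    labels = np.asarray(patient_labels, dtype=bool)
    if len(ids) != len(labels):
        raise ShapeError("patient_ids and labels length mismatch")
    if len(ids) < n_folds:
        raise InvalidParameterError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    pos = [ids[i] for i in rng.permutation(len(ids)) if labels[i]]
    neg = [ids[i] for i in rng.permutation(len(ids)) if not labels[i]]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for k, pid in enumerate(pos):
        folds[k % n_folds].append(pid)
    base, rem = divmod(len(ids), n_folds)
    targets = [base + (1 if k < rem else 0) for k in range(n_folds)]
    # fill smallest-deficit folds first so sizes come out balanced
    for pid in neg:
        k = int(np.argmax([t - len(f) for t, f in zip(targets, folds)]))
        folds[k].append(pid)
    out = []
    for k in range(n_folds):
        test = tuple(folds[k])
        train = tuple(p for j, f in enumerate(folds) if j != k for p in f)
        out.append((train, test))
    return out


def plan_from_patient_folds(
    segment_patients: list[str],
    fold: tuple[tuple[str, ...], tuple[str, ...]],
    seed: int = 0,
    val_fraction: float = 0.2,
) -> SplitPlan:
    """Map a patient-level fold to segment indices, holding out validation
    segments from the training patients (never from test patients)."""
    train_p, test_p = set(fold[0]), set(fold[1])
    pats = np.asarray([str(p) for p in segment_patients])
    test_idx = np.nonzero(np.isin(pats, list(test_p)))[0]
    pool = np.nonzero(np.isin(pats, list(train_p)))[0]
    rng = np.random.default_rng(seed)
    pool = rng.permutation(pool)
    n_val = int(round(val_fraction * len(pool)))
    return SplitPlan(
        "inter", pool[n_val:], pool[:n_val], test_idx, seed,
        test_patients=tuple(sorted(test_p)), train_patients=tuple(sorted(train_p)),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts and SE/SP/PPV/ACC (percent), optionally AUC."""

    TP: int
    TN: int
    FP: int
    FN: int
    SE: float
    SP: float
    PPV: float
    ACC: float
    AUC: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("TP", "TN", "FP", "FN", "SE", "SP", "PPV", "ACC", "AUC")}


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """SE, SP, PPV and ACC (percent) from thresholded scores.

    ``scores`` are recurrence probabilities (or already-binary predictions);
    ``labels`` are 1 for recurrence.  Undefined rates (zero denominator)
    come back as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(int)
    if scores.shape != labels.shape:
        raise ShapeError("scores and labels length mismatch")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return MetricsReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        SE=_rate(tp, tp + fn, "SE"),
        SP=_rate(tn, tn + fp, "SP"),
        PPV=_rate(tp, tp + fp, "PPV"),
        ACC=_rate(tp + tn, tp + tn + fp + fn, "ACC"),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank/Mann-Whitney formulation, midrank ties)."""
    labels = np.asarray(labels).reshape(-1).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined for single-class labels")
    return float(sklearn.metrics.roc_auc_score(labels, np.asarray(scores, float).reshape(-1)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    lr0: float = 1e-3
    decay: float = 1e-4
    seed: int = 0


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = float("nan")


def train_model(
    model: RecurrenceNet3D,
    train_sequences: np.ndarray,
    train_labels: np.ndarray,
    val_sequences: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[RecurrenceNet3D, TrainHistory]:
    """Mini-batch Adam training with 1/t learning-rate decay.

    Sequences are ``(N, H, W, T)`` stacks in [0, 1]; labels are 1 for
    recurrence.  After every epoch the validation accuracy is evaluated and
    the best-scoring weights are kept; the returned model carries the best
    checkpoint.
    """
    cfg = cfg or TrainConfig()
    if len(train_sequences) == 0 or len(val_sequences) == 0:
        raise ConfigurationError("empty train or validation partition")
    y_train = np.asarray(train_labels).reshape(-1).astype(int)
    y_val = np.asarray(val_labels).reshape(-1).astype(int)
    opt = Adam(model.parameters(), lr0=cfg.lr0, decay=cfg.decay)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best_state = model.state_dict()
    x_train = np.asarray(train_sequences, dtype=np.float64)

    from .model.network import predict  # local import to avoid cycle at module load

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            x = sequences_to_batch(x_train[idx])
            probs = model.predict_proba(x)
            loss = model.loss(probs, y_train[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        probs_val = predict(model, val_sequences)[:, 1]
        acc = float(np.mean((probs_val >= 0.5).astype(int) == y_val)) * 100.0
        history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        history.val_acc.append(acc)
        if not (acc <= history.best_val_acc):  # first epoch or improvement
            history.best_val_acc = acc
            history.best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history
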