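"""Classification and segmentation metrics, 180-degree clip augmentation,
and k-fold cross-validation reporting (per-fold rows plus a mean +/- sd
summary row)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ContractError, DataError
from .phantom import PRESENT

POSITIVE = PRESENT


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """Metrics in [0,1]; a metric with a zero denominator is None, not 0."""

    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    accuracy: float | None = None
    f1: float | None = None
    npv: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_percent(self) -> dict:
        return {k: (None if v is None else 100.0 * v)
                for k, v in self.as_dict().items()}


def _as_binary(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if lab in (POSITIVE, 1, True):
            out.append(1)
        elif lab in ("absent", 0, False):
            out.append(0)
        else:
            raise ContractError(f"labels must be binary, got {lab!r}")
    return np.array(out, dtype=int)


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """TP/FP/TN/FN tallies with "present" (1) as the positive class."""
    pred = _as_binary(pred_labels)
    true = _as_binary(true_labels)
    if len(pred) != len(true):
        raise ContractError(
            f"length mismatch: {len(pred)} predictions, {len(true)} labels")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (true == 1))),
        FP=int(np.sum((pred == 1) & (true == 0))),
        TN=int(np.sum((pred == 0) & (true == 0))),
        FN=int(np.sum((pred == 0) & (true == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(cc: ConfusionCounts) -> MetricReport:
    if cc.total == 0:
        raise DataError("empty confusion counts")
    sens = _ratio(cc.TP, cc.TP + cc.FN)
    spec = _ratio(cc.TN, cc.TN + cc.FP)
    prec = _ratio(cc.TP, cc.TP + cc.FP)
    acc = (cc.TP + cc.TN) / cc.total
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    npv = _ratio(cc.TN, cc.TN + cc.FN)
    return MetricReport(sensitivity=sens, specificity=spec, precision=prec,
                        accuracy=acc, f1=f1, npv=npv)


def dice_iou(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(Dice, IoU) overlap of two binary masks; identical empties give (1,1)."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    size_sum = int(a.sum() + b.sum())
    dice = 1.0 if size_sum == 0 else 2.0 * inter / size_sum
    iou = 1.0 if union == 0 else inter / union
    return dice, iou


def roc_auc(scores, true_labels) -> float:
    """Trapezoidal area under the ROC curve; tied scores contribute half."""
    scores = np.asarray(scores, dtype=float)
    true = _as_binary(true_labels)
    if len(scores) != len(true):
        raise ContractError("scores and labels differ in length")
    n_pos = int(true.sum())
    n_neg = len(true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = true[order]
    # cumulative TP/FP at each distinct threshold (descending scores)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(t_sorted)[idx]
    fps = np.cumsum(1 - t_sorted)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def augment_rotate180(clip: np.ndarray) -> np.ndarray:
    """Rotate every frame 180 degrees: (r, c) -> (H-1-r, W-1-c)."""
    clip = np.asarray(clip)
    if clip.ndim < 3:
        raise ContractError(f"expected (T,H,W[,C]) clip, got shape {clip.shape}")
    return clip[:, ::-1, ::-1].copy()


@dataclass
class FoldAssignment:
    fold_of: np.ndarray     # fold index per sample
    k: int

    def __iter__(self):
        for fold in range(self.k):
            test = np.nonzero(self.fold_of == fold)[0]
            train = np.nonzero(self.fold_of != fold)[0]
            yield train, test


def kfold_split(n: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle into k folds whose sizes differ by at most one."""
    if k < 2 or k > n:
        raise ContractError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        fold_of[perm[start:start + size]] = fold
        start += size
    return FoldAssignment(fold_of=fold_of, k=k)


def summarize_folds(reports: list[MetricReport],
                    sd_mode: str = "population") -> dict:
    """Mean +/- sd per metric across folds, skipping undefined entries."""
    if sd_mode not in ("population", "sample"):
        raise ContractError("sd_mode must be 'population' or 'sample'")
    ddof = 0 if sd_mode == "population" else 1
    out = {}
    for f in fields(MetricReport):
        vals = [getattr(r, f.name) for r in reports
                if getattr(r, f.name) is not None]
        if not vals:
            out[f.name] = (None, None)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
        out[f.name] = (mean, sd)
    return out


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricReport]
    summary: dict = field(default_factory=dict)

    def table_rows(self) -> list[dict]:
        """Per-fold percentage rows plus an 'Ave.' row."""
        rows = []
        for i, rep in enumerate(self.fold_reports):
            rows.append({"fold": f"Fold{i + 1}", **rep.as_percent()})
        ave = {"fold": "Ave."}
        for name, (mean, sd) in self.summary.items():
            ave[name] = None if mean is None else f"{100 * mean:.0f} +/- {100 * sd:.0f}"
        rows.append(ave)
        return rows


def cross_validate(builder, clips: np.ndarray, labels, train_fn, predict_fn,
                   k: int = 5, seed: int = 0, augment: bool = True,
                   sd_mode: str = "population") -> CrossValidationResult:
    """Train a fresh model per fold and evaluate on the held-out fold.

    builder() -> model; train_fn(model, x, y) -> model;
    predict_fn(model, x) -> P(present) array. Rotation augmentation is
    applied to the training folds only, after splitting, so augmented
    copies never straddle the train/test boundary.
    """
    x_all = np.asarray(clips)
    y_all = _as_binary(labels)
    assignment = kfold_split(len(y_all), k=k, seed=seed)
    reports = []
    for train_idx, test_idx in assignment:
        x_tr, y_tr = x_all[train_idx], y_all[train_idx]
        if augment:
            x_tr = np.concatenate(
                [x_tr, np.stack([augment_rotate180(c) for c in x_tr])])
            y_tr = np.concatenate([y_tr, y_tr])
        model = builder()
        model = train_fn(model, x_tr, y_tr)
        probs = np.asarray(predict_fn(model, x_all[test_idx]))
        pred = (probs >= 0.5).astype(int)
        rep = classification_metrics(confusion(pred, y_all[test_idx]))
        if len(np.unique(y_all[test_idx])) == 2:
            rep.auc = roc_auc(probs, y_all[test_idx])
        reports.append(rep)
    return CrossValidationResult(fold_reports=reports,
                                 summary=summarize_folds(reports, sd_mode))
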