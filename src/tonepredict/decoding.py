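"""Time-resolved multiclass decoding of tone identity.

A shrinkage-regularized linear discriminant classifier is trained at every
training time point on random-condition trials and evaluated at every testing
time point (temporal generalization).  Within the random condition evaluation
uses stratified fivefold cross-validation; testing on other conditions is
cross-decoding, so the classifier is fit once on all training trials.  Chance
level is 1/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .simulate import EpochsContainer


@dataclass
class DecoderConfig:
    shrinkage: str | float | None = "auto"
    n_folds: int = 5
    train_condition: str = "random"
    train_window_s: tuple | None = None   # restrict training times; None = all
    exclude_omissions: bool = True
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TimeGenMatrix:
    """Decoding accuracy indexed by (training time, testing time)."""

    acc: np.ndarray
    train_times_s: np.ndarray
    test_times_s: np.ndarray
    test_condition: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.acc.shape != (len(self.train_times_s), len(self.test_times_s)):
            raise ValueError("accuracy matrix shape must match the time axes")
        if np.any(self.acc < 0) or np.any(self.acc > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    def diagonal(self) -> np.ndarray:
        """Per-timepoint accuracy (train time == test time); requires equal axes."""
        if not np.array_equal(self.train_times_s, self.test_times_s):
            raise ValueError("diagonal undefined for unequal time axes")
        return np.diag(self.acc).copy()


@dataclass
class ConfusionTensor:
    """Per-testing-time K x K confusion counts (rows true tone, cols predicted)."""

    counts: np.ndarray            # T x K x K
    test_times_s: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.test_times_s):
            raise ValueError("time axis mismatch")
        if self.counts.shape[1] != self.counts.shape[2]:
            raise ValueError("confusion matrices must be square")

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    def row_normalized(self) -> "ConfusionTensor":
        if self.normalized:
            return self
        sums = self.counts.sum(axis=2, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("cannot row-normalize: some true class has no test trials")
        return ConfusionTensor(
            counts=self.counts / sums,
            test_times_s=self.test_times_s,
            normalized=True,
        )


def _make_lda(cfg: DecoderConfig) -> LinearDiscriminantAnalysis:
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=cfg.shrinkage)


def _window_indices(times: np.ndarray, window: tuple | None) -> np.ndarray:
    if window is None:
        return np.arange(len(times))
    lo, hi = window
    idx = np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))
    if len(idx) == 0:
        raise ValueError(f"window {window} contains no samples of the epoch grid")
    return idx


def cv_decode_random(
    epochs: EpochsContainer, cfg: DecoderConfig | None = None
) -> tuple[np.ndarray, TimeGenMatrix, ConfusionTensor]:
    """Stratified k-fold decoding within the training condition.

    Returns the per-timepoint accuracy time course (the diagonal of the
    temporal-generalization matrix, computed from the same folds), the full
    temporal-generalization matrix, and the per-testing-time confusion tensor
    of the diagonal (train time == test time) predictions.
    """
    cfg = cfg or DecoderConfig()
    sel = epochs.sound_trials(cfg.train_condition) if cfg.exclude_omissions else epochs.select(
        epochs.condition == cfg.train_condition
    )
    X, y, times = sel.data, sel.labels, sel.times_s
    classes = np.unique(y)
    K = len(classes)
    counts = np.bincount(np.searchsorted(classes, y))
    if np.any(counts < cfg.n_folds):
        raise ValueError(
            "stratification error: every tone class needs at least one trial per fold"
        )
    train_idx_t = _window_indices(times, cfg.train_window_s)
    T_test = len(times)
    acc = np.zeros((len(train_idx_t), T_test))
    # diagonal confusion tensor: predictions at test time == train time
    conf = np.zeros((len(train_idx_t), K, K))
    n_test_total = 0

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
    y_codes = np.searchsorted(classes, y)
    for tr, te in skf.split(X[:, :, 0], y):
        n_te = len(te)
        n_test_total += n_te
        Xte_flat = np.transpose(X[te], (0, 2, 1)).reshape(n_te * T_test, -1)
        for row, t_tr in enumerate(train_idx_t):
            clf = _make_lda(cfg)
            clf.fit(X[tr, :, t_tr], y[tr])
            pred = clf.predict(Xte_flat).reshape(n_te, T_test)
            acc[row] += (pred == y[te, None]).sum(axis=0)
            pred_diag = np.searchsorted(classes, pred[:, t_tr])
            np.add.at(conf[row], (y_codes[te], pred_diag), 1)
    acc /= n_test_total

    tg = TimeGenMatrix(
        acc=acc,
        train_times_s=times[train_idx_t],
        test_times_s=times,
        test_condition=cfg.train_condition,
        subject_id=epochs.subject_id,
    )
    # accuracy time course = diagonal of the temporal-generalization matrix
    timecourse = acc[np.arange(len(train_idx_t)), train_idx_t]
    return timecourse, tg, ConfusionTensor(counts=conf, test_times_s=times[train_idx_t])


def cross_decode(
    train_epochs: EpochsContainer,
    test_epochs: EpochsContainer,
    cfg: DecoderConfig | None = None,
) -> TimeGenMatrix:
    """Train once per training time on all training trials; test everywhere.

    No cross-validation: training and testing conditions differ, so the scheme
    is already cross-decoding.  Pre-stimulus testing times are included, which
    realizes training on the post-stimulus and testing on the pre-stimulus
    interval when the training window is post-stimulus.
    """
    cfg = cfg or DecoderConfig()
    if train_epochs.n_channels != test_epochs.n_channels:
        raise ValueError("channel mismatch between training and testing containers")
    tr = (
        train_epochs.sound_trials(cfg.train_condition)
        if cfg.exclude_omissions
        else train_epochs.select(train_epochs.condition == cfg.train_condition)
    )
    te = test_epochs.sound_trials() if cfg.exclude_omissions else test_epochs
    Xtr, ytr = tr.data, tr.labels
    Xte, yte = te.data, te.labels
    train_idx_t = _window_indices(tr.times_s, cfg.train_window_s)
    T_test = len(te.times_s)
    n_te = Xte.shape[0]
    Xte_flat = np.transpose(Xte, (0, 2, 1)).reshape(n_te * T_test, -1)
    acc = np.zeros((len(train_idx_t), T_test))
    for row, t_tr in enumerate(train_idx_t):
        clf = _make_lda(cfg)
        clf.fit(Xtr[:, :, t_tr], ytr)
        pred = clf.predict(Xte_flat).reshape(n_te, T_test)
        acc[row] = (pred == yte[:, None]).mean(axis=0)
    cond = str(te.condition[0]) if len(te.condition) else ""
    return TimeGenMatrix(
        acc=acc,
        train_times_s=tr.times_s[train_idx_t],
        test_times_s=te.times_s,
        test_condition=cond,
        subject_id=test_epochs.subject_id,
    )


def bias_score(conf: ConfusionTensor, cyclic: bool = True) -> np.ndarray:
    """Difference between mean mass on the first and second upper diagonals.

    Per testing time, on row-normalized confusion matrices: mean of cells
    (true i -> predicted i+1) minus mean of cells (true i -> predicted i+2),
    diagonals taken along the designated transition direction.  With
    ``cyclic=True`` (default) the diagonals wrap at K; otherwise only the
    strictly upper cells enter.
    """
    if conf.K < 3:
        raise ValueError("bias score requires at least 3 classes")
    p = conf.row_normalized().counts
    K = conf.K
    idx = np.arange(K)
    if cyclic:
        first = p[:, idx, (idx + 1) % K].mean(axis=1)
        second = p[:, idx, (idx + 2) % K].mean(axis=1)
    else:
        i1 = idx[:-1]
        i2 = idx[:-2]
        first = p[:, i1, i1 + 1].mean(axis=1)
        second = p[:, i2, i2 + 2].mean(axis=1)
    return first - second


def group_average(matrices: list[TimeGenMatrix]) -> TimeGenMatrix:
    """Element-wise mean of per-subject temporal-generalization matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    ref = matrices[0]
    for m in matrices[1:]:
        if not (
            np.array_equal(m.train_times_s, ref.train_times_s)
            and np.array_equal(m.test_times_s, ref.test_times_s)
        ):
            raise ValueError("time axes differ across subjects")
    return TimeGenMatrix(
        acc=np.mean([m.acc for m in matrices], axis=0),
        train_times_s=ref.train_times_s,
        test_times_s=ref.test_times_s,
        test_condition=ref.test_condition,
        subject_id="group",
    )
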