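"""Neural prediction scores.

Per-condition temporal-generalization matrices are collapsed to one score
matrix per subject: either the slope of decoding accuracy over the entropy
conditions (four-condition designs) or the ordered-minus-random accuracy
difference (two-condition designs).  For inference the score matrix is averaged
over a post-stimulus training window (default 470–570 ms) and read out on the
pre-stimulus testing interval (default −400–0 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import TimeGenMatrix


@dataclass(frozen=True)
class WindowSpec:
    train_window_s: tuple = (0.470, 0.570)
    test_window_s: tuple = (-0.400, 0.0)

    def __post_init__(self) -> None:
        if self.train_window_s[0] >= self.train_window_s[1]:
            raise ValueError("training window must have lo < hi")
        if self.test_window_s[0] >= self.test_window_s[1]:
            raise ValueError("testing window must have lo < hi")


@dataclass
class PredictionScoreMatrix:
    score: np.ndarray             # train x test
    train_times_s: np.ndarray
    test_times_s: np.ndarray
    mode: str                     # "beta_slope" | "ordered_minus_random"
    subject_id: str
    condition_coding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.score.shape != (len(self.train_times_s), len(self.test_times_s)):
            raise ValueError("score matrix shape must match the time axes")


def _check_axes(matrices: list[TimeGenMatrix]) -> None:
    ref = matrices[0]
    for m in matrices[1:]:
        if not (
            np.array_equal(m.train_times_s, ref.train_times_s)
            and np.array_equal(m.test_times_s, ref.test_times_s)
        ):
            raise ValueError("time axes differ across condition matrices")


def beta_slopes(
    acc_by_condition: list[TimeGenMatrix], coding=None
) -> PredictionScoreMatrix:
    """Pointwise OLS slope of accuracy on the condition code, intercept discarded.

    Conditions must be supplied in increasing-regularity order (random first,
    ordered last); the default coding is equally spaced integers 0..C−1.
    """
    if len(acc_by_condition) < 2:
        raise ValueError("need at least two conditions for a slope")
    _check_axes(acc_by_condition)
    coding = np.asarray(
        coding if coding is not None else np.arange(len(acc_by_condition)), dtype=float
    )
    if len(coding) != len(acc_by_condition):
        raise ValueError("coding length must match the number of conditions")
    if np.any(np.diff(coding) <= 0):
        raise ValueError("condition coding must be strictly increasing")
    stack = np.stack([m.acc for m in acc_by_condition])  # C x train x test
    c = coding - coding.mean()
    slope = np.tensordot(c, stack - stack.mean(axis=0), axes=(0, 0)) / (c @ c)
    ref = acc_by_condition[0]
    return PredictionScoreMatrix(
        score=slope,
        train_times_s=ref.train_times_s,
        test_times_s=ref.test_times_s,
        mode="beta_slope",
        subject_id=ref.subject_id,
        condition_coding=coding,
    )


def diff_score(
    acc_ordered: TimeGenMatrix, acc_random: TimeGenMatrix
) -> PredictionScoreMatrix:
    """Element-wise ordered-minus-random accuracy difference."""
    _check_axes([acc_ordered, acc_random])
    return PredictionScoreMatrix(
        score=acc_ordered.acc - acc_random.acc,
        train_times_s=acc_ordered.train_times_s,
        test_times_s=acc_ordered.test_times_s,
        mode="ordered_minus_random",
        subject_id=acc_ordered.subject_id,
    )


def _clip_window(times: np.ndarray, window: tuple, what: str) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        warnings.warn(
            f"{what} window {window} exceeds the epoch ({times[0]:.3f}, {times[-1]:.3f}) "
            "and is clipped to it",
            stacklevel=3,
        )
    idx = np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))
    if len(idx) == 0:
        raise ValueError(f"{what} window {window} is empty after clipping to the epoch")
    return idx


def window_score(
    score: PredictionScoreMatrix,
    w: WindowSpec | None = None,
    at_test_time_s: float | None = -0.380,
) -> dict:
    """Collapse a score matrix over the training window.

    Returns the per-testing-time course of the training-window mean, the scalar
    mean over the testing window, and (optionally) the value at a named testing
    time such as −380 ms, taken at the nearest sample.
    """
    w = w or WindowSpec()
    tr_idx = _clip_window(score.train_times_s, w.train_window_s, "training")
    te_idx = _clip_window(score.test_times_s, w.test_window_s, "testing")
    course = score.score[tr_idx].mean(axis=0)
    out = {
        "test_times_s": score.test_times_s.copy(),
        "timecourse": course,
        "window_mean": float(course[te_idx].mean()),
    }
    if at_test_time_s is not None:
        i = int(np.argmin(np.abs(score.test_times_s - at_test_time_s)))
        out["at_time_s"] = float(score.test_times_s[i])
        out["at_time_value"] = float(course[i])
    return out
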