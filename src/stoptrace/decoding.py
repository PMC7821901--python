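"""Frame-wise population decoding of locomotor state.

A linear maximum-margin classifier (hinge loss, L2 regularization,
class-balanced weighting) predicts per frame whether the animal is walking
(forward) or stationary from the simultaneous activity of all recorded
cells.  Validation is a jack-knife: the recording is split into a random
contiguous 20% test chunk and an 80% training remainder, five times, and
ROC/AUC on the held-out chunks is averaged.  Contiguous chunks (rather than
i.i.d. frames) limit temporal leakage from calcium autocorrelation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .behavior import STATE_BACKWARD, STATE_FORWARD
from .errors import DegenerateAnalysisError, InputError

logger = logging.getLogger(__name__)


@dataclass
class PopulationMatrix:
    """Frames × cells activity with per-frame walking labels."""

    X: np.ndarray            # (n_valid_frames, n_cells)
    y: np.ndarray            # 1 = walking (forward), 0 = stationary
    frame_index: np.ndarray  # original frame of each row
    cell_ids: list
    rate_hz: float
    n_backward_excluded: int = 0

    @property
    def single_class(self) -> bool:
        return np.unique(self.y).size < 2


def build_population_matrix(
    traces,
    states,
    rate_hz: float,
    valid_mask=None,
    cell_ids=None,
) -> PopulationMatrix:
    """Assemble the decoding design matrix from per-cell traces and states.

    ``traces`` is (frames × cells) (an array or DataFrame on the calcium
    clock); ``states`` the per-frame locomotor labels on the same clock.
    Backward-locomotion frames are ambiguous for "walking or not" and are
    excluded (counted in the result).
    """
    if hasattr(traces, "to_numpy"):
        if cell_ids is None:
            cell_ids = list(traces.columns)
        traces = traces.to_numpy(dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    states = np.asarray(states)
    if traces.shape[0] != states.size:
        raise InputError(
            f"traces ({traces.shape[0]} frames) and states ({states.size}) "
            "are not on the same clock"
        )
    if cell_ids is None:
        cell_ids = [f"cell_{j}" for j in range(traces.shape[1])]
    if valid_mask is None:
        valid_mask = np.ones(states.size, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)

    backward = states == STATE_BACKWARD
    keep = valid_mask & ~backward
    n_backward = int((valid_mask & backward).sum())
    if n_backward:
        logger.info("excluding %d backward-locomotion frames from decoding", n_backward)
    frame_index = np.flatnonzero(keep)
    y = (states[keep] == STATE_FORWARD).astype(int)
    pm = PopulationMatrix(
        X=traces[keep],
        y=y,
        frame_index=frame_index,
        cell_ids=list(cell_ids),
        rate_hz=rate_hz,
        n_backward_excluded=n_backward,
    )
    if pm.single_class:
        logger.warning("population matrix has a single class; decoding untrainable")
    return pm


def roc_auc(scores, labels):
    """ROC curve by sweeping all unique thresholds, AUC by trapezoid rule.

    The AUC equals the Mann–Whitney U normalization: the probability that a
    random positive frame outscores a random negative one.
    Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateAnalysisError("ROC undefined with a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


@dataclass
class DecodingReport:
    split_aucs: list
    mean_auc: float
    roc_curves: list           # (fpr, tpr) per split
    predicted: np.ndarray      # per-row predicted label from the full-data fit
    frame_index: np.ndarray
    rate_hz: float
    n_splits: int
    resampled_splits: int = 0

    def predicted_full(self, n_frames: int, fill: int = -1) -> np.ndarray:
        """Per-frame predicted labels on the original clock (fill = no prediction)."""
        out = np.full(n_frames, fill, dtype=int)
        out[self.frame_index] = self.predicted
        return out

    def to_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "split_aucs": [float(a) for a in self.split_aucs],
            "mean_auc": float(self.mean_auc),
            "resampled_splits": self.resampled_splits,
        }


def _contiguous_split(n: int, test_frac: float, rng: np.random.Generator):
    test_len = max(1, int(round(test_frac * n)))
    start = int(rng.integers(0, n - test_len + 1))
    test = np.zeros(n, dtype=bool)
    test[start : start + test_len] = True
    return ~test, test


class StopDecoder(ClassifierMixin, BaseEstimator):
    """Linear maximum-margin walking/stationary decoder.

    Thin sklearn estimator around :class:`~sklearn.svm.LinearSVC`
    (hinge loss, L2 penalty, class-balanced weights, fixed C — no tuning).
    ``evaluate`` runs the five-fold random contiguous-chunk jack-knife.
    """

    def __init__(self, C: float = 1.0, n_splits: int = 5, train_frac: float = 0.8,
                 max_iter: int = 5000, random_state=None):
        self.C = C
        self.n_splits = n_splits
        self.train_frac = train_frac
        self.max_iter = max_iter
        self.random_state = random_state

    def _svc(self) -> LinearSVC:
        return LinearSVC(
            C=self.C,
            loss="hinge",
            class_weight="balanced",
            max_iter=self.max_iter,
            random_state=0,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DegenerateAnalysisError("cannot fit a decoder on single-class data")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.svc_ = self._svc().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(np.asarray(X, dtype=float))

    def evaluate(self, X, y, rate_hz: float = 20.0, frame_index=None) -> DecodingReport:
        """Jack-knife train/eval: random contiguous 80/20 splits, ROC per split."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise DegenerateAnalysisError("decoding undefined on single-class data")
        rng = np.random.default_rng(self.random_state)
        n = y.size
        aucs, curves = [], []
        resampled = 0
        for _ in range(self.n_splits):
            for attempt in range(50):
                train, test = _contiguous_split(n, 1.0 - self.train_frac, rng)
                if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
                    break
                resampled += 1
            else:
                raise DegenerateAnalysisError(
                    "could not find a split with both classes in train and test"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                svc = self._svc().fit(X[train], y[train])
            scores = svc.decision_function(X[test])
            fpr, tpr, auc = roc_auc(scores, y[test])
            aucs.append(auc)
            curves.append((fpr, tpr))
        if resampled:
            logger.info("resampled %d degenerate split(s)", resampled)
        self.fit(X, y)
        predicted = self.predict(X)
        if frame_index is None:
            frame_index = np.arange(n)
        return DecodingReport(
            split_aucs=aucs,
            mean_auc=float(np.mean(aucs)),
            roc_curves=curves,
            predicted=predicted,
            frame_index=np.asarray(frame_index, dtype=int),
            rate_hz=rate_hz,
            n_splits=self.n_splits,
            resampled_splits=resampled,
        )


def jackknife_train_eval(
    matrix: PopulationMatrix,
    n_splits: int = 5,
    train_frac: float = 0.8,
    C: float = 1.0,
    seed=None,
) -> DecodingReport:
    """Functional front-end to :meth:`StopDecoder.evaluate`."""
    if matrix.single_class:
        raise DegenerateAnalysisError("decoding undefined on single-class data")
    dec = StopDecoder(C=C, n_splits=n_splits, train_frac=train_frac, random_state=seed)
    return dec.evaluate(matrix.X, matrix.y, rate_hz=matrix.rate_hz,
                        frame_index=matrix.frame_index)


def unpredicted_stops(
    predicted_full: np.ndarray,
    stop_onset_frames,
    rate_hz: float,
    window_s: float = 1.5,
) -> np.ndarray:
    """Boolean flag per stop: True when the decoder never predicts the
    stationary state within ``window_s`` after the stop onset.

    Frames without a prediction (e.g. excluded backward frames) are ignored.
    """
    predicted_full = np.asarray(predicted_full)
    onsets = np.asarray(stop_onset_frames, dtype=int)
    w = max(1, int(round(window_s * rate_hz)))
    flags = np.empty(onsets.size, dtype=bool)
    for i, f in enumerate(onsets):
        win = predicted_full[f : min(f + w, predicted_full.size)]
        flags[i] = not np.any(win == 0)
    return flags
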