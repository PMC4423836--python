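"""Evolutionary train/test-split and feature-mask optimization.

The protocol has two coupled searches.  The *T&T* stage evolves a binary
membership vector splitting individuals into training and testing halves
so that each half is statistically representative of the whole: the
fitness of a split is the *minimum* over the two cross-directions
(train on A, test on B; train on B, test on A) of held-out accuracy,
averaged over the enabled learner bank — a split is only as good as its
worse direction.  The *IS* stage then evolves a feature mask (one bit per
indicator column) maximizing held-out accuracy on the frozen split using
only the masked columns.  Learners never see testing-set labels during
fitting; outcome indicator columns are excluded from the feature space by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ga
from .datamodel import IndicatorMatrix
from .ga import GAConfig, GAResult
from .learners import LearnerBank


class TwistError(ValueError):
    pass


@dataclass
class SplitAssignment:
    """Binary membership over individuals; 1 = training set."""

    membership: np.ndarray
    target_fraction: float = 0.5

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=np.int8)
        if self.membership.sum() in (0, len(self.membership)):
            raise TwistError("both split halves must be nonempty")

    def validate_classes(self, outcome: np.ndarray) -> None:
        outcome = np.asarray(outcome)
        for side in (1, 0):
            y = outcome[self.membership == side]
            if np.unique(y).size < 2:
                raise TwistError("each split half needs at least one case and one control")

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.membership == 1)

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(self.membership == 0)


@dataclass
class FeatureMask:
    """Presence/absence bits over indicator columns (outcome excluded)."""

    bits: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if len(self.bits) != len(self.labels):
            raise TwistError("mask length must match number of indicator columns")
        if self.bits.sum() == 0:
            raise TwistError("a feature mask must select at least one column")

    @property
    def selected(self) -> list[str]:
        return [lab for lab, b in zip(self.labels, self.bits) if b]

    @property
    def removed(self) -> list[str]:
        return [lab for lab, b in zip(self.labels, self.bits) if not b]


def confusion_cost(pred, obs, kind: str = "misclassification") -> float:
    """Cost of a prediction vector against the observed outcome, in [0, 1].

    ``misclassification`` is 1 - accuracy (the off-diagonal rate of the
    confusion matrix); ``rmse`` is the root mean square error, an
    alternative cost for the same role.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise TwistError("prediction and observation lengths differ")
    if kind == "misclassification":
        return float(np.mean(pred != obs))
    if kind == "rmse":
        return float(np.sqrt(np.mean((pred - obs) ** 2)))
    raise TwistError(f"unknown cost kind {kind!r}")


def _features(indicators: IndicatorMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(indicators, IndicatorMatrix):
        frame = indicators.feature_frame()
        return frame.to_numpy(dtype=float), list(frame.columns)
    X = np.asarray(indicators, dtype=float)
    return X, [f"col{i}" for i in range(X.shape[1])]


def _bank_accuracy(bank: LearnerBank, X_tr, y_tr, X_te, y_te, cost_kind) -> float:
    preds = bank.predictions(X_tr, y_tr, X_te)
    return float(np.mean([1.0 - confusion_cost(p, y_te, cost_kind) for p in preds]))


def _split_repair(outcome: np.ndarray, target_fraction: float):
    """Repair closure keeping splits at the target size with both classes
    present on both sides."""
    n = len(outcome)
    n_train = int(round(target_fraction * n))
    n_train = min(max(n_train, 2), n - 2)
    case_idx = np.flatnonzero(outcome == 1)
    control_idx = np.flatnonzero(outcome == 0)

    if len(case_idx) < 2 or len(control_idx) < 2:
        raise TwistError("need at least two cases and two controls to split")

    def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        bits = bits.astype(np.int8).copy()
        # enforce the training-set size by flipping random surplus bits
        diff = int(bits.sum()) - n_train
        if diff != 0:
            pool = np.flatnonzero(bits == (1 if diff > 0 else 0))
            take = rng.choice(pool, size=abs(diff), replace=False)
            bits[take] = 0 if diff > 0 else 1
        # both classes on both sides: swap a donor of the missing class with
        # an opposite-class row already on that side (size-preserving)
        for _ in range(len(bits)):
            fixed = True
            for cls_idx, other_idx in ((case_idx, control_idx), (control_idx, case_idx)):
                for side in (1, 0):
                    if not (bits[cls_idx] == side).any():
                        donor = rng.choice(cls_idx[bits[cls_idx] != side])
                        swap_pool = other_idx[bits[other_idx] == side]
                        swap = rng.choice(swap_pool)
                        bits[donor], bits[swap] = side, 1 - side
                        fixed = False
            if fixed:
                break
        return bits

    return repair


def optimize_split(
    indicators: IndicatorMatrix | np.ndarray,
    outcome: np.ndarray,
    ga_config: GAConfig,
    bank: LearnerBank,
    target_fraction: float = 0.5,
    cost_kind: str = "misclassification",
) -> tuple[SplitAssignment, GAResult]:
    """Evolve a representative train/test split.

    Fitness of a membership vector is ``min`` over the two cross-prediction
    directions of learner-bank accuracy: both halves must predict each
    other well, which penalizes unrepresentative subsets.
    """
    X, _ = _features(indicators)
    outcome = np.asarray(outcome, dtype=int)
    if np.unique(outcome).size < 2:
        raise TwistError("both outcome classes must be present")
    repair = _split_repair(outcome, target_fraction)

    def fitness(bits: np.ndarray) -> float:
        a = bits == 1
        acc_ab = _bank_accuracy(bank, X[a], outcome[a], X[~a], outcome[~a], cost_kind)
        acc_ba = _bank_accuracy(bank, X[~a], outcome[~a], X[a], outcome[a], cost_kind)
        return min(acc_ab, acc_ba)

    result = ga.evolve(fitness, len(outcome), ga_config, repair=repair)
    split = SplitAssignment(result.best, target_fraction)
    split.validate_classes(outcome)
    return split, result


def stratified_split(
    outcome: np.ndarray, target_fraction: float = 0.5, seed: int = 0
) -> SplitAssignment:
    """Plain stratified random split — the non-evolved baseline, also used
    wherever a frozen split is needed without the T&T search."""
    outcome = np.asarray(outcome, dtype=int)
    rng = np.random.default_rng(seed)
    bits = np.zeros(len(outcome), dtype=np.int8)
    for cls in (0, 1):
        idx = np.flatnonzero(outcome == cls)
        n_tr = max(1, int(round(target_fraction * len(idx))))
        bits[rng.choice(idx, size=n_tr, replace=False)] = 1
    split = SplitAssignment(bits, target_fraction)
    split.validate_classes(outcome)
    return split


def _mask_repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, len(bits))] = 1
    return bits


def select_features(
    indicators: IndicatorMatrix | np.ndarray,
    outcome: np.ndarray,
    split: SplitAssignment,
    ga_config: GAConfig,
    bank: LearnerBank,
    cost_kind: str = "misclassification",
) -> tuple[FeatureMask, GAResult]:
    """Evolve the minimal predictive feature mask on a frozen split.

    Fitness of a mask is ``1 - confusion_cost`` on the testing set using
    only the masked columns, averaged over the enabled learners.  Returns
    the best-ever mask and the GA result carrying the (non-decreasing)
    best-fitness trace.
    """
    X, labels = _features(indicators)
    outcome = np.asarray(outcome, dtype=int)
    split.validate_classes(outcome)
    tr, te = split.train_idx, split.test_idx
    X_tr, X_te = X[tr], X[te]
    y_tr, y_te = outcome[tr], outcome[te]

    def fitness(bits: np.ndarray) -> float:
        cols = bits.astype(bool)
        return _bank_accuracy(bank, X_tr[:, cols], y_tr, X_te[:, cols], y_te, cost_kind)

    result = ga.evolve(fitness, X.shape[1], ga_config, repair=_mask_repair)
    return FeatureMask(result.best, labels), result
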