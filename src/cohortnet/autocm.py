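"""Auto Contractive Map (Auto-CM) similarity learning.

The Auto-CM is a three-layer adaptive network trained on the records of a
binary indicator matrix.  Each input node carries a *mono-connection*
weight ``v_i`` to its hidden twin, and the hidden layer is fully connected
to the output layer by the square matrix ``W``.  On each record ``x``:

    hidden   m^h_i = x_i (1 - v_i / C)
    net      Net_i = (1/C) sum_j m^h_j W_ji
    output   m^t_i = m^h_i (1 - Net_i / C)

    dv_i  = (x_i - m^h_i)(1 - v_i / C)
    dW_ji = (m^h_i - m^t_i)(1 - W_ji / C) m^h_j

``C`` is the contraction parameter (default: the number of columns).  As
training proceeds every ``v_i`` rises monotonically towards ``C``, the
hidden signal contracts to zero, and ``W`` freezes having absorbed the
co-activation structure of the columns: strongly co-occurring indicator
variables end with large mutual weights.  The symmetrized, ``C``-normalized
weight matrix is read as a variable-similarity matrix in [0, 1] — a fuzzy
degree of joint membership rather than a linear correlation — and
``1 - S`` is the distance the spanning-tree stage consumes.

Per-record deltas are *averaged* over each epoch and applied at the epoch
boundary, which makes training invariant to record order and keeps the
update bounded (a raw per-epoch sum would scale with the number of records
and could push ``v`` past ``C``).  For a single record the mean equals the
sum, so the one-step dynamics are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AutoCMError(ValueError):
    pass


@dataclass
class AutoCMModel:
    """Trained Auto-CM state."""

    C: float
    v: np.ndarray
    W: np.ndarray
    labels: list[str]
    epochs_run: int
    converged: bool
    output_trace: np.ndarray  # mean output signal per epoch
    v_trace: np.ndarray | None = None  # (epochs+1, N) when tracked

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "v": self.v.tolist(),
            "W": self.W.tolist(),
            "labels": self.labels,
            "epochs_run": self.epochs_run,
            "converged": self.converged,
        }


@dataclass
class SimilarityMatrix:
    """Symmetric variable x variable similarity in [0, 1]; diagonal = 1."""

    S: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape[0] != self.S.shape[1] or len(self.labels) != self.S.shape[0]:
            raise AutoCMError("similarity matrix shape does not match labels")
        if not np.allclose(self.S, self.S.T):
            raise AutoCMError("similarity matrix must be symmetric")
        if self.S.min() < 0 or self.S.max() > 1:
            raise AutoCMError("similarity entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


def _epoch_deltas(X: np.ndarray, v: np.ndarray, W: np.ndarray, C: float):
    """Vectorized per-epoch mean deltas and the mean output signal."""
    Mh = X * (1.0 - v / C)               # records x N
    Net = Mh @ W / C                     # Net_i = sum_j Mh_j W_ji
    Mt = Mh * (1.0 - Net / C)
    dv = ((X - Mh) * (1.0 - v / C)).mean(axis=0)
    dW = (1.0 - W / C) * (Mh.T @ (Mh - Mt)) / X.shape[0]
    return dv, dW, float(np.abs(Mt).mean())


def train_autocm(
    X,
    labels: list[str] | None = None,
    C: float | None = None,
    max_epochs: int = 1000,
    tol: float = 1e-6,
    init_eps: float = 0.01,
    track_v: bool = False,
) -> AutoCMModel:
    """Train the contraction dynamics on a [0, 1] matrix.

    Deterministic: weights start at the uniform ``init_eps`` (zero
    initialization provably stalls the dynamics) and records are processed
    as a batch each epoch.  Training stops when the mean output signal
    drops below ``tol`` or after ``max_epochs``.

    Raises
    ------
    AutoCMError
        On entries outside [0, 1], fewer than 2 columns, or any constant
        column (a constant column never contracts relative to the others;
        the caller must drop it).
    """
    if isinstance(X, pd.DataFrame):
        labels = labels or [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise AutoCMError("need a 2-D matrix with at least 2 columns")
    if np.isnan(X).any() or X.min() < 0 or X.max() > 1:
        raise AutoCMError("input entries must lie in [0, 1]")
    constant = np.flatnonzero(X.max(axis=0) == X.min(axis=0)) if X.shape[0] > 1 else np.array([])
    if constant.size:
        names = [labels[i] if labels else str(i) for i in constant]
        raise AutoCMError(
            f"constant column(s) {names}: drop them before training"
        )
    n, N = X.shape
    labels = labels or [f"col{i}" for i in range(N)]
    C = float(C if C is not None else N)
    if C <= 0:
        raise AutoCMError("contraction parameter C must be positive")

    v = np.full(N, float(init_eps))
    W = np.full((N, N), float(init_eps))
    out_trace: list[float] = []
    v_hist = [v.copy()] if track_v else None
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        dv, dW, mean_out = _epoch_deltas(X, v, W, C)
        v = v + dv
        W = W + dW
        out_trace.append(mean_out)
        if track_v:
            v_hist.append(v.copy())
        if mean_out < tol:
            converged = True
            break

    return AutoCMModel(
        C=C,
        v=v,
        W=W,
        labels=list(labels),
        epochs_run=epoch,
        converged=converged,
        output_trace=np.array(out_trace),
        v_trace=np.array(v_hist) if track_v else None,
    )


def saturating_C(X) -> float:
    """Contraction parameter placing the dynamics in their saturating regime.

    Under the batch-mean dynamics the total log-growth of a connection
    weight is approximately ``N x̄² ln(C/eps) / C`` (``N`` columns, overall
    activation mean ``x̄``): with the conservative default ``C = N`` the
    weights never leave the neighbourhood of their initialization, while
    for ``C <~ N x̄²`` strongly co-occurring columns saturate toward ``C``.
    ``C = max(2, N x̄²)`` is the self-consistent marginal value — the
    largest contraction at which genuine co-activation still drives weights
    onto the interpretable [0, 1] similarity scale.  The mapping stages use
    this value so the 0.33/0.66/0.84 strength read-out and the MRG noise
    floor are meaningful.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return float(max(2.0, X.shape[1] * X.mean() ** 2))


def similarity_matrix(model: AutoCMModel) -> SimilarityMatrix:
    """Symmetrize and normalize the trained connection matrix:
    ``S_ij = (W_ij + W_ji) / (2C)``, clipped to [0, 1], diagonal set to 1."""
    if model.epochs_run == 0:
        raise AutoCMError("model has not been trained")
    S = np.clip((model.W + model.W.T) / (2.0 * model.C), 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S=S, labels=list(model.labels))


def to_distances(sim: SimilarityMatrix) -> np.ndarray:
    """Monotone similarity-to-distance transform ``D = 1 - S`` (zero
    diagonal), so minimum-distance trees maximize total similarity."""
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return D


#: similarity-strength cut-points, read as w <= .33 null/very-low,
#: .33 < w <= .66 quite-low, .66 < w <= .84 quite-high, w > .84 very-high
STRENGTH_BINS = (
    (0.33, "null/very-low"),
    (0.66, "quite-low"),
    (0.84, "quite-high"),
)

#: conventional noise floor below which a link is not worth re-introducing
NOISE_FLOOR = 0.33


def classify_strength(w: float) -> str:
    """Qualitative label for a similarity weight in [0, 1]."""
    if not 0 <= w <= 1:
        raise AutoCMError(f"similarity {w} outside [0, 1]")
    for cut, label in STRENGTH_BINS:
        if w <= cut:
            return label
    return "very-high"
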