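"""Surround-suppression gate for velocity estimates.

A contextual mechanism modelled on centre-surround interactions of
direction-selective MT neurons: an object's velocity estimate is compared
with the mean estimate of its spatial neighbours (a circular surround of
diameter ``d``), and a binary activation

    f = H( H(||v_hat - v_bar|| - theta1) - fbar_w - theta2 )

decides whether the estimate is pulled toward the surround mean.  ``H`` is
the Heaviside step (strict: H(0) = 0), ``theta1`` a velocity-difference
threshold, ``fbar_w`` the mean of the object's own past activations over a
history window of duration ``w``, and ``theta2`` a history threshold.
Under this form a *persistently* active gate switches itself off once the
historical average exceeds ``1 - theta2``: past suppression counts as prior
evidence that the deviation is expected.

When active, the gate removes a fraction ``s`` of the deviation:
``v_g = v_hat - f * s * (v_hat - v_bar)``; with ``s = 1`` the estimate is
replaced by the surround mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SuppressionParams",
    "SuppressionState",
    "neighbor_lists",
    "surround_mean",
    "surround_mean_all",
    "activation",
    "gate",
    "step_history",
]


@dataclass
class SuppressionParams:
    """Parameters of the surround-suppression gate.

    theta1 : velocity-difference threshold [units/s]
    theta2 : history threshold, dimensionless, in [0, 1]
    window_ms : history window duration [ms]
    diameter : surround neighbourhood diameter [units]
    strength : fraction s in [0, 1] of the deviation removed when active
    """

    theta1: float
    theta2: float = 0.5
    window_ms: float = 30.0
    diameter: float = 1.0
    strength: float = 1.0
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.theta1 < 0:
            raise ValueError("theta1 must be >= 0")
        if not 0.0 <= self.theta2 <= 1.0:
            raise ValueError("theta2 must be in [0, 1]")
        if self.window_ms < 0:
            raise ValueError("window_ms must be >= 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")

    def window_length(self, dt_step: float) -> int:
        """Ring-buffer length: ceil(window_ms / step duration in ms)."""
        if self.window_ms == 0:
            return 0
        step_ms = dt_step * 1000.0
        return int(np.ceil(self.window_ms / step_ms))


class SuppressionState:
    """Per-object ring buffer of past binary activations.

    The buffer length is fixed for a run (``window_length`` entries); the
    historical average ``fbar`` uses only past steps, never the current
    activation, and is 0 while the buffer is empty (or the window is 0).
    """

    def __init__(self, n_objects: int, window_length: int):
        self.n_objects = int(n_objects)
        self.window_length = int(window_length)
        self._buf = np.zeros((max(self.window_length, 1), self.n_objects), dtype=np.uint8)
        self._filled = 0
        self._head = 0
        self.last_activation = np.zeros(self.n_objects, dtype=np.uint8)

    def fbar(self) -> np.ndarray:
        """Historical mean activation per object (0 where no history)."""
        if self.window_length == 0 or self._filled == 0:
            return np.zeros(self.n_objects)
        return self._buf[: self._filled].sum(axis=0) / self._filled

    def push(self, activations: np.ndarray) -> None:
        activations = np.asarray(activations, dtype=np.uint8)
        if activations.shape != (self.n_objects,):
            raise ValueError("activations must have one entry per object")
        self.last_activation = activations
        if self.window_length == 0:
            return
        self._buf[self._head] = activations
        self._head = (self._head + 1) % self.window_length
        self._filled = min(self._filled + 1, self.window_length)


def step_history(state: SuppressionState, activations: np.ndarray) -> SuppressionState:
    """Push the current activations, evicting entries older than the window."""
    state.push(activations)
    return state


def neighbor_lists(positions: np.ndarray, diameter: float):
    """Equal-weight surround-averaging operator for the current frame.

    Returns ``(A, counts)`` where ``A`` is a sparse (N, N) row-stochastic
    matrix averaging over each object's neighbours (centre excluded; rows
    with no neighbours are zero) and ``counts`` the per-object neighbour
    count.  Two objects are neighbours when their Euclidean distance is at
    most ``diameter / 2``.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    tree = cKDTree(positions)
    pairs = tree.query_pairs(diameter / 2.0, output_type="ndarray")
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        rows = cols = np.empty(0, dtype=np.intp)
    counts = np.bincount(rows, minlength=n)
    data = 1.0 / counts[rows] if len(rows) else np.empty(0)
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return A, counts


def surround_mean_all(
    v_hat: np.ndarray, A, counts: np.ndarray, include_self: bool = False
) -> np.ndarray:
    """Mean predicted velocity of each object's surround (equal weights).

    With ``include_self`` the centre object's own estimate enters the
    average (a consensus over the neighbourhood rather than a pure
    surround).  Objects with an empty surround get their own estimate back,
    which guarantees the gate stays inactive for them.
    """
    v_hat = np.asarray(v_hat, dtype=float)
    v_bar = A @ v_hat
    if include_self:
        c = counts[:, None]
        v_bar = (v_bar * c + v_hat) / (c + 1)
    empty = counts == 0
    if empty.any():
        v_bar[empty] = v_hat[empty]
    return v_bar


def surround_mean(positions, state, params: SuppressionParams, i: int) -> np.ndarray:
    """Surround-average velocity for a single object.

    ``state`` may be anything exposing predicted velocities via
    ``predict_velocity`` semantics; an (N, 2) array of predicted velocities
    is also accepted directly.
    """
    from . import coding

    if isinstance(state, np.ndarray):
        v_hat = state
    else:
        v_hat = coding.predict_velocity(state)
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions - positions[i], axis=1)
    mask = (d <= params.diameter / 2.0) & (np.arange(len(d)) != i)
    if not mask.any():
        return v_hat[i].copy()
    if params.include_self:
        mask = mask.copy()
        mask[i] = True
    return v_hat[mask].mean(axis=0)


def activation(
    v_hat: np.ndarray,
    v_bar: np.ndarray,
    fbar: np.ndarray | float,
    params: SuppressionParams,
) -> np.ndarray:
    """Binary suppression activation per object.

    ``f = H(H(||v_hat - v_bar|| - theta1) - fbar - theta2)`` with a strict
    Heaviside (H(0) = 0).  Accepts (N, 2) arrays or single 2-vectors.
    """
    v_hat = np.atleast_2d(np.asarray(v_hat, dtype=float))
    v_bar = np.atleast_2d(np.asarray(v_bar, dtype=float))
    dev = np.linalg.norm(v_hat - v_bar, axis=-1)
    inner = (dev - params.theta1 > 0).astype(float)
    f = (inner - np.asarray(fbar) - params.theta2 > 0).astype(np.uint8)
    return f if f.size > 1 else f.reshape(())[()]


def gate(
    v_hat: np.ndarray,
    v_bar: np.ndarray,
    f: np.ndarray,
    params: SuppressionParams,
) -> np.ndarray:
    """Gated velocity: v_g = v_hat - f * s * (v_hat - v_bar)."""
    v_hat = np.asarray(v_hat, dtype=float)
    v_bar = np.asarray(v_bar, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if v_hat.ndim == 2:
        f_arr = f_arr.reshape(-1, 1)
    return v_hat - f_arr * params.strength * (v_hat - v_bar)
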