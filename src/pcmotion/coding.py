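"""Two-level predictive-coding network for motion decomposition.

An object's velocity is modelled as a weighted sum of latent 2-D motion
sources,

    v_hat_i = sum_j u_ij r_j,

with weights ``u_ij`` ("motion strengths") boxed to [0, 1] and sources
``r_j`` shared across objects.  A second level predicts the sources
themselves through a weight matrix U2, so the network minimises the
sum-of-squares prediction error over both levels,

    E = 1/2 ||v_obs - U1 r1||^2 + 1/2 ||r1 - U2 r2||^2.

Activities relax by explicit-Euler gradient descent on E at a fast
timescale; weights follow a Hebbian (error x activity) gradient step at a
slow timescale and are projected back to [0, 1] and onto the connectivity
mask after each step.

The printed dynamics in the source literature carry a leading minus on
``-gamma * dE/dr`` whose expansion is ambiguous; this module implements
true gradient *descent*: ``dr1 = +gamma (U1^T e0 - e1)``,
``dU1 = +eta e0 r1^T`` (contracted over the two velocity components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkState",
    "Errors",
    "LearningParams",
    "DivergenceError",
    "observed_velocity",
    "predict_velocity",
    "compute_errors",
    "objective",
    "update_activities",
    "update_weights",
    "init_state",
]


class DivergenceError(FloatingPointError):
    """The Euler integration of the network dynamics produced non-finite values."""


@dataclass
class NetworkState:
    """Activities and weights of the two-level network.

    r1 : (M, 2) level-1 source activities (velocities, units/s)
    r2 : (M2, 2) level-2 activities (acceleration-like)
    U1 : (N, M) weights in [0, 1]; zero wherever ``mask`` is zero
    U2 : (M, M2) level-2 weights (identity by default, optionally learned)
    mask : (N, M) binary connectivity (shared/individual structure)
    """

    r1: np.ndarray
    r2: np.ndarray
    U1: np.ndarray
    U2: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.U1 = np.asarray(self.U1, dtype=float)
        self.U2 = np.asarray(self.U2, dtype=float)
        self.mask = np.asarray(self.mask)
        N, M = self.U1.shape
        if self.mask.shape != (N, M):
            raise ValueError("mask shape must match U1")
        if self.r1.shape != (M, 2):
            raise ValueError(f"r1 must have shape ({M}, 2)")
        if self.U2.shape[0] != M or self.r2.shape != (self.U2.shape[1], 2):
            raise ValueError("U2/r2 shapes inconsistent with r1")
        self.validate()

    @property
    def n_objects(self) -> int:
        return self.U1.shape[0]

    @property
    def n_sources(self) -> int:
        return self.U1.shape[1]

    def validate(self) -> None:
        for name in ("r1", "r2", "U1", "U2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DivergenceError(f"non-finite values in {name}")
        if np.any(self.U1 < -1e-12) or np.any(self.U1 > 1 + 1e-12):
            raise ValueError("U1 entries must lie in [0, 1]")
        if np.any(self.U1[~self.mask.astype(bool)] != 0):
            raise ValueError("U1 must be zero outside the connectivity mask")

    def copy(self) -> "NetworkState":
        return NetworkState(
            r1=self.r1.copy(),
            r2=self.r2.copy(),
            U1=self.U1.copy(),
            U2=self.U2.copy(),
            mask=self.mask.copy(),
        )


@dataclass
class Errors:
    """Per-level prediction errors: e0 = v_obs - U1 r1 (N, 2); e1 = r1 - U2 r2 (M, 2)."""

    e0: np.ndarray
    e1: np.ndarray


@dataclass
class LearningParams:
    """Update rates for the two-timescale dynamics.

    gamma : activity (inference) rate [1/s]
    eta : weight learning rate
    inner_iters : activity updates per stimulus frame
    dt_int : integration step of the dynamics [s]
    """

    gamma: float
    eta: float
    inner_iters: int = 50
    dt_int: float = 1e-3

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.eta < 0 or self.dt_int <= 0:
            raise ValueError("gamma, dt_int must be > 0 and eta >= 0")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")


def init_state(
    mask: np.ndarray,
    rng: np.random.Generator,
    m2: int | None = None,
    weight_init: tuple[float, float] = (0.0, 0.1),
) -> NetworkState:
    """Initial state: r1 = r2 = 0, small random positive weights on the mask.

    U2 is identity-sized (M2 = M) and initialised to the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    N, M = mask.shape
    m2 = M if m2 is None else m2
    U1 = np.where(mask, rng.uniform(*weight_init, size=(N, M)), 0.0)
    return NetworkState(
        r1=np.zeros((M, 2)),
        r2=np.zeros((m2, 2)),
        U1=U1,
        U2=np.eye(M, m2),
        mask=mask,
    )


def observed_velocity(stimulus, frame_index: int) -> np.ndarray:
    """Per-object velocity at ``frame_index``: position increment over dt.

    The level-0 input to the network is the per-frame velocity, so the
    first-level error is a velocity residual.
    """
    if frame_index < 1:
        raise ValueError("frame_index must be >= 1 (no previous frame)")
    if frame_index >= stimulus.n_frames:
        raise ValueError(f"frame_index {frame_index} out of range")
    return (
        stimulus.positions[frame_index] - stimulus.positions[frame_index - 1]
    ) / stimulus.dt


def predict_velocity(state: NetworkState) -> np.ndarray:
    """Predicted object velocities v_hat = U1 r1, shape (N, 2)."""
    return state.U1 @ state.r1


def compute_errors(v_obs: np.ndarray, state: NetworkState) -> Errors:
    """Prediction errors at both levels."""
    e0 = np.asarray(v_obs, dtype=float) - predict_velocity(state)
    e1 = state.r1 - state.U2 @ state.r2
    return Errors(e0=e0, e1=e1)


def objective(v_obs: np.ndarray, state: NetworkState) -> float:
    """Sum-of-squares prediction error E = 1/2 (||e0||^2 + ||e1||^2)."""
    err = compute_errors(v_obs, state)
    return 0.5 * (np.sum(err.e0 ** 2) + np.sum(err.e1 ** 2))


def update_activities(
    state: NetworkState, v_obs: np.ndarray, params: LearningParams
) -> NetworkState:
    """One explicit Euler step of the activity dynamics (gradient descent on E).

    r1 <- r1 + dt gamma (U1^T e0 - e1);  r2 <- r2 + dt gamma U2^T e1.
    Errors are recomputed before the step.  Returns a new state.
    """
    err = compute_errors(v_obs, state)
    step = params.gamma * params.dt_int
    r1 = state.r1 + step * (state.U1.T @ err.e0 - err.e1)
    r2 = state.r2 + step * (state.U2.T @ err.e1)
    if not (np.all(np.isfinite(r1)) and np.all(np.isfinite(r2))):
        raise DivergenceError(
            f"activity update diverged (gamma*dt_int = {step:g})"
        )
    return NetworkState(r1=r1, r2=r2, U1=state.U1, U2=state.U2, mask=state.mask)


def update_weights(
    state: NetworkState,
    errors: Errors,
    params: LearningParams,
    learn_u2: bool = False,
) -> NetworkState:
    """One Hebbian weight step, projected to [0, 1] and onto the mask.

    dU1[i, j] accumulates the dot product e0_i . r1_j (the unique bilinear
    scalar consistent with dE/du_ij for scalar weights and 2-D activities).
    U2 is frozen by default.
    """
    step = params.eta * params.dt_int
    dU1 = errors.e0 @ state.r1.T  # (N, M), contracted over velocity components
    U1 = np.clip(state.U1 + step * dU1, 0.0, 1.0)
    U1 = np.where(state.mask.astype(bool), U1, 0.0)
    U2 = state.U2
    if learn_u2:
        U2 = U2 + step * (errors.e1 @ state.r2.T)
    return NetworkState(r1=state.r1, r2=state.r2, U1=U1, U2=U2, mask=state.mask)
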