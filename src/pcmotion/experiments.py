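"""Convergence-time metric and parameter-sweep experiments.

Coherent motion is considered detected when the tracked motion strength
stabilises -- successive-frame changes of the mean shared strength of the
signal dots stay below a tolerance (0.05 units by default) for a sustained
run of frames -- while the detected direction lies within 45 degrees of the
true coherent direction.  Convergence time is the number of stimulus frames
to that point times the frame interval, reported in ms.

The sweeps reproduce the study's random-dot-kinematogram experiments:
convergence time as a function of the signal fraction (noise level), of the
suppression-history window duration, of the suppression threshold, and of
dot density.  Trials are seeded deterministically from the base seed and the
cell's parameter values, so per-cell results are independent of sweep order
and fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ModelConfig, TraceLog, run
from .stimuli import generate_rdk


def signal_fraction(ratio: float) -> float:
    """Convert a signal-to-noise *dots ratio* (Ns/Nn) to the signal fraction.

    The sweep grids are expressed as the ratio of signal dots to noise dots;
    the RDK generator takes the coherence (signal fraction Ns/N), so a ratio
    r maps to r / (1 + r).
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ratio / (1.0 + ratio)

__all__ = [
    "ConvergenceResult",
    "MotionStrengthSummary",
    "SweepResult",
    "convergence_time",
    "direction_error_deg",
    "motion_strength_summary",
    "sweep_noise",
    "signal_fraction",
    "sweep_window",
    "sweep_threshold_noise",
    "sweep_density",
]

#: RDK generator settings used by the sweeps: the study's stimulus scaled
#: down to 200 dots (density preserved) and 10 s trials.
SWEEP_RDK_DEFAULTS = dict(
    n_dots=200,
    coherent_velocity=0.01,
    noise_velocity=0.01,
    dt=0.05,
    duration=10.0,
)


class InsufficientDataError(ValueError):
    """The trace is too short to evaluate the convergence criterion."""


@dataclass
class ConvergenceResult:
    """Outcome of the convergence-time metric for one run.

    ``time_ms = steps * dt * 1000``; when the run never stabilises,
    ``converged`` is False and ``time_ms`` is the censoring bound (the full
    trace duration).
    """

    converged: bool
    steps: int
    time_ms: float
    direction_error_deg: float


def _direction_error(v: np.ndarray, truth_dir: np.ndarray) -> float:
    norm = np.linalg.norm(v)
    tnorm = np.linalg.norm(truth_dir)
    if norm < 1e-12 or not np.isfinite(tnorm) or tnorm < 1e-12:
        return float("nan")
    cosang = float(np.dot(v, truth_dir) / (norm * tnorm))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def direction_error_deg(trace: TraceLog, truth_dir: np.ndarray) -> float:
    """Angle (deg) between the final shared-source velocity and the truth."""
    return _direction_error(trace.r_shared[-1], np.asarray(truth_dir, float))


def _truth_direction_from_meta(trace: TraceLog) -> np.ndarray:
    meta = trace.stimulus_meta or {}
    cv = meta.get("coherent_velocity")
    if cv is not None and cv != 0:
        return np.array([math.copysign(1.0, cv), 0.0])
    return np.array([1.0, 0.0])


def _tracked_series(trace: TraceLog) -> np.ndarray:
    """Mean shared strength over signal dots (all dots if unlabelled)."""
    mask = trace.label_mask("signal")
    if not mask.any():
        mask = np.ones(trace.n_objects, dtype=bool)
    return trace.shared_strength[:, mask].mean(axis=1)


def convergence_time(
    trace: TraceLog,
    stability_tol: float = 0.05,
    sustain_frames: int = 10,
    direction_tol_deg: float = 45.0,
    truth_direction: np.ndarray | None = None,
) -> ConvergenceResult:
    """First frame after which the tracked strength is stable and the
    direction correct.

    Stability means the mean shared strength of the signal dots changes by
    less than ``stability_tol`` between every pair of successive frames for
    ``sustain_frames`` consecutive frames; the detected direction at the end
    of that window must err by less than ``direction_tol_deg``.
    """
    if trace.n_frames < sustain_frames + 1:
        raise InsufficientDataError(
            f"trace has {trace.n_frames} frames; need > {sustain_frames}"
        )
    truth = (
        np.asarray(truth_direction, float)
        if truth_direction is not None
        else _truth_direction_from_meta(trace)
    )
    series = _tracked_series(trace)
    stable = np.abs(np.diff(series)) < stability_tol
    # stable[k] compares frames k and k+1 of the trace.
    window_ok = (
        np.convolve(stable.astype(int), np.ones(sustain_frames, dtype=int), "valid")
        == sustain_frames
    )
    censor = ConvergenceResult(
        converged=False,
        steps=trace.n_frames,
        time_ms=trace.n_frames * trace.dt * 1000.0,
        direction_error_deg=_direction_error(trace.r_shared[-1], truth),
    )
    for k in np.flatnonzero(window_ok):
        # Stable diffs k .. k+sustain-1 span trace frames k .. k+sustain;
        # convergence is declared at the window's last frame.
        end = k + sustain_frames
        err = _direction_error(trace.r_shared[end], truth)
        if np.isfinite(err) and err < direction_tol_deg:
            return ConvergenceResult(
                converged=True,
                steps=end,
                time_ms=end * trace.dt * 1000.0,
                direction_error_deg=err,
            )
    return censor


@dataclass
class MotionStrengthSummary:
    """Group mean and time series of individual and shared motion strengths.

    ``rate_individual_per_ms`` / ``rate_shared_per_ms`` are the mean absolute
    per-frame change of the group-mean series divided by the frame duration
    in ms (a rate of change, reported alongside the plain bounded means).
    """

    group: str
    n_dots: int
    empty: bool
    mean_individual: float
    mean_shared: float
    series_individual: np.ndarray
    series_shared: np.ndarray
    rate_individual_per_ms: float
    rate_shared_per_ms: float


def motion_strength_summary(trace: TraceLog, group: str) -> MotionStrengthSummary:
    """Mean over dots and frames of individual/shared strength for a label group."""
    mask = trace.label_mask(group)
    n = int(mask.sum())
    if n == 0:
        return MotionStrengthSummary(
            group=group,
            n_dots=0,
            empty=True,
            mean_individual=float("nan"),
            mean_shared=float("nan"),
            series_individual=np.empty(0),
            series_shared=np.empty(0),
            rate_individual_per_ms=float("nan"),
            rate_shared_per_ms=float("nan"),
        )
    si = trace.individual_strength[:, mask].mean(axis=1)
    ss = trace.shared_strength[:, mask].mean(axis=1)
    dt_ms = trace.dt * 1000.0
    rate = lambda s: float(np.mean(np.abs(np.diff(s))) / dt_ms) if len(s) > 1 else 0.0
    return MotionStrengthSummary(
        group=group,
        n_dots=n,
        empty=False,
        mean_individual=float(si.mean()),
        mean_shared=float(ss.mean()),
        series_individual=si,
        series_shared=ss,
        rate_individual_per_ms=rate(si),
        rate_shared_per_ms=rate(ss),
    )


# ---------------------------------------------------------------------------
# Sweeps


@dataclass
class SweepResult:
    """Tidy per-trial records plus a per-cell summary.

    ``data`` has one row per (parameter cell, trial) with the trial seed,
    the convergence flag, time and direction error.  ``summary`` aggregates
    per cell: mean and standard deviation of the convergence time over
    *converged* trials (censored runs are counted in ``n_censored``, never
    silently folded into the mean).
    """

    data: pd.DataFrame
    param_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        df = self.data
        grouped = df.groupby(self.param_names, sort=True)
        out = grouped.agg(
            n_trials=("time_ms", "size"),
            n_converged=("converged", "sum"),
        )
        conv = df[df["converged"]].groupby(self.param_names, sort=True)["time_ms"]
        out["mean_time_ms"] = conv.mean()
        out["std_time_ms"] = conv.std()
        out["n_censored"] = out["n_trials"] - out["n_converged"]
        return out.reset_index()

    def argmin_cell(self, param: str | None = None):
        """Parameter value of the cell with the smallest mean convergence time.

        Cells with no converged trials are excluded (their mean is undefined).
        """
        param = param or self.param_names[0]
        s = self.summary.dropna(subset=["mean_time_ms"])
        if s.empty:
            return None
        return s.loc[s["mean_time_ms"].idxmin(), param]


def trial_seed(base_seed: int, cell_key: tuple, trial: int) -> int:
    """Deterministic per-trial seed from the base seed and the cell's values.

    Depends only on the parameter values (not their position in the grid),
    so re-ordering a sweep leaves every cell's trials unchanged.
    """
    ints = [int(base_seed) & 0x7FFFFFFF, int(trial)]
    for v in cell_key:
        ints.append(int(round(float(v) * 1e6)) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


def _run_trial(
    cell: dict,
    trial: int,
    base_seed: int,
    base_config: ModelConfig,
    rdk_kwargs: dict,
    sustain_frames: int,
    stability_tol: float,
) -> dict:
    seed = trial_seed(base_seed, tuple(cell.values()), trial)
    stim = generate_rdk(seed=seed, **rdk_kwargs)
    config = replace(base_config, seed=seed)
    trace = run(stim, config)
    res = convergence_time(
        trace, stability_tol=stability_tol, sustain_frames=sustain_frames
    )
    return {
        **cell,
        "trial": trial,
        "seed": seed,
        "converged": res.converged,
        "time_ms": res.time_ms,
        "direction_error_deg": res.direction_error_deg,
    }


def _sweep(
    cells: list[dict],
    config_for_cell,
    rdk_for_cell,
    n_trials: int,
    base_seed: int,
    base_config: ModelConfig | None,
    rdk_kwargs: dict | None,
    sustain_frames: int = 10,
    stability_tol: float = 0.05,
    meta: dict | None = None,
) -> SweepResult:
    base_config = base_config or ModelConfig()
    defaults = {**SWEEP_RDK_DEFAULTS, **(rdk_kwargs or {})}
    records = []
    for cell in cells:
        cfg = config_for_cell(base_config, cell)
        rdk = rdk_for_cell(defaults, cell)
        for trial in range(n_trials):
            records.append(
                _run_trial(
                    cell, trial, base_seed, cfg, rdk, sustain_frames, stability_tol
                )
            )
    data = pd.DataFrame.from_records(records)
    return SweepResult(
        data=data,
        param_names=list(cells[0].keys()),
        meta={"base_seed": base_seed, "n_trials": n_trials, **(meta or {})},
    )


def sweep_noise(
    ratios,
    window_ms: float = 30.0,
    n_trials: int = 30,
    base_config: ModelConfig | None = None,
    base_seed: int = 0,
    rdk_kwargs: dict | None = None,
    **metric_kwargs,
) -> SweepResult:
    """Convergence time as a function of the signal fraction (noise level).

    Higher noise (lower signal fraction) is expected to lengthen
    convergence.  ``window_ms`` sets the suppression-history window for the
    whole sweep.
    """
    cells = [{"ratio": float(r)} for r in ratios]
    return _sweep(
        cells,
        lambda cfg, cell: replace(cfg, window_ms=window_ms),
        lambda rdk, cell: {**rdk, "signal_ratio": signal_fraction(cell["ratio"])},
        n_trials,
        base_seed,
        base_config,
        rdk_kwargs,
        meta={"window_ms": window_ms},
        **metric_kwargs,
    )


def sweep_window(
    durations_ms,
    ratio: float = 0.4,
    n_trials: int = 30,
    base_config: ModelConfig | None = None,
    base_seed: int = 0,
    rdk_kwargs: dict | None = None,
    **metric_kwargs,
) -> SweepResult:
    """Convergence time as a function of the history-window duration.

    The per-duration mean convergence time is expected to be U-shaped: some
    history damps the response to noise, too much history over-weights the
    past.  ``SweepResult.argmin_cell()`` gives the minimising duration.
    """
    cells = [{"window_ms": float(w)} for w in durations_ms]
    return _sweep(
        cells,
        lambda cfg, cell: replace(cfg, window_ms=cell["window_ms"]),
        lambda rdk, cell: {**rdk, "signal_ratio": signal_fraction(ratio)},
        n_trials,
        base_seed,
        base_config,
        rdk_kwargs,
        meta={"ratio": ratio},
        **metric_kwargs,
    )


def sweep_threshold_noise(
    theta1_grid,
    ratio_grid,
    n_trials: int = 30,
    base_config: ModelConfig | None = None,
    base_seed: int = 0,
    rdk_kwargs: dict | None = None,
    **metric_kwargs,
) -> SweepResult:
    """Convergence-time matrix over suppression threshold x signal fraction."""
    cells = [
        {"theta1": float(t), "ratio": float(r)} for t in theta1_grid for r in ratio_grid
    ]
    return _sweep(
        cells,
        lambda cfg, cell: replace(cfg, theta1=cell["theta1"]),
        lambda rdk, cell: {**rdk, "signal_ratio": signal_fraction(cell["ratio"])},
        n_trials,
        base_seed,
        base_config,
        rdk_kwargs,
        **metric_kwargs,
    )


def sweep_density(
    densities,
    n_trials: int = 10,
    base_config: ModelConfig | None = None,
    base_seed: int = 0,
    rdk_kwargs: dict | None = None,
    **metric_kwargs,
) -> SweepResult:
    """Convergence time per dot density (field size fixed, dot count varied)."""
    defaults = {**SWEEP_RDK_DEFAULTS, **(rdk_kwargs or {})}
    field_size = defaults.get("field_size") or math.sqrt(
        defaults["n_dots"] / 500.0
    )
    cells = [{"density": float(d)} for d in densities]

    def rdk_for_cell(rdk, cell):
        n = max(2, int(round(cell["density"] * field_size ** 2)))
        out = {**rdk, "n_dots": n, "field_size": field_size}
        out.setdefault("signal_ratio", 0.5)
        return out

    return _sweep(
        cells,
        lambda cfg, cell: cfg,
        rdk_for_cell,
        n_trials,
        base_seed,
        base_config,
        rdk_kwargs,
        meta={"field_size": field_size},
        **metric_kwargs,
    )
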