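"""Psychophysical dot-stimulus generators.

Three classical displays used to probe hierarchical motion perception are
generated as frame-indexed 2-D dot trajectories:

* **Johansson display** -- three collinear dots oscillating horizontally, the
  middle dot along a diagonal, perceived as shared translation plus vertical
  motion of the middle dot.
* **Duncker wheel** -- a hub dot translating linearly and a rim dot on a
  cycloid, perceived as translation plus rotation.
* **Random dot kinematogram (RDK)** -- a field of dots of which a fraction
  (the coherence, or signal ratio) translates in a common direction while the
  rest move at fixed speed in random directions.

All generators are pure functions of their parameters (and seed, for the
RDK): the same call reproduces the same trajectories bit for bit.
Coordinates are continuous spatial "units", origin at the field centre,
x rightward, y upward; frame index is 0-based and time is ``frame * dt``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "StimulusError",
    "StimulusParseError",
    "generate_johansson",
    "generate_duncker",
    "generate_rdk",
    "read_stimulus",
    "write_stimulus",
]


class StimulusError(ValueError):
    """Invalid stimulus parameters or contents."""


class StimulusParseError(StimulusError):
    """A trajectory file could not be parsed into a valid stimulus."""


@dataclass
class Stimulus:
    """Frame-indexed 2-D dot trajectories with ground-truth labels.

    Attributes
    ----------
    positions : ndarray, shape (T, N, 2)
        Dot positions per frame, in spatial units.
    dt : float
        Seconds per frame.
    labels : list of str, length N
        Per-dot category tag (``outer``/``middle``, ``hub``/``rim``,
        ``signal``/``noise``).
    truth : ndarray, shape (N, 2)
        Per-dot ground-truth shared velocity [units/s].  For oscillatory
        displays this is the peak shared velocity; its direction is what
        matters for direction-error metrics.
    meta : dict
        Generator name, parameters and seed.
    """

    positions: np.ndarray
    dt: float
    labels: list[str]
    truth: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise StimulusError(
                f"positions must have shape (T, N, 2), got {self.positions.shape}"
            )
        if self.n_frames < 2:
            raise StimulusError("a stimulus needs at least 2 frames")
        if self.n_dots < 1:
            raise StimulusError("a stimulus needs at least 1 dot")
        if not self.dt > 0:
            raise StimulusError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.positions)):
            raise StimulusError("positions contain non-finite values")
        if len(self.labels) != self.n_dots:
            raise StimulusError(
                f"{len(self.labels)} labels for {self.n_dots} dots"
            )
        if self.truth.shape != (self.n_dots, 2):
            raise StimulusError(
                f"truth must have shape (N, 2), got {self.truth.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds (T-1 inter-frame intervals)."""
        return (self.n_frames - 1) * self.dt

    def velocities(self) -> np.ndarray:
        """Per-frame observed velocities, shape (T-1, N, 2), in units/s."""
        return np.diff(self.positions, axis=0) / self.dt

    def label_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels], dtype=bool)


def _check_timing(frequency_or_none, dt: float, duration: float) -> int:
    if dt <= 0:
        raise StimulusError(f"dt must be positive, got {dt}")
    if duration <= dt:
        raise StimulusError("duration must cover at least two frames")
    n_frames = int(math.floor(duration / dt)) + 1
    return n_frames


def generate_johansson(
    frequency: float = 0.5,
    h_amplitude: float = 20.3,
    v_amplitude: float = math.cos(math.radians(45.0)) * 20.3,
    dt: float = 1.0 / 60.0,
    duration: float = 24.0,
    separation: float = 10.0,
) -> Stimulus:
    """Three vertically aligned dots oscillating back and forth.

    The two outer dots oscillate horizontally with amplitude ``h_amplitude``;
    the middle dot oscillates diagonally (horizontal component
    ``h_amplitude``, vertical component ``v_amplitude``) so the three dots
    stay collinear at every frame.  Dots start at the oscillation midpoint
    moving rightward (sine phase).

    Parameters follow the study's defaults: 0.5 Hz, horizontal amplitude
    20.3 units, vertical amplitude cos(45 deg)*20.3, frame interval 1/60 s.
    """
    if frequency <= 0:
        raise StimulusError(f"frequency must be positive, got {frequency}")
    if h_amplitude < 0 or v_amplitude < 0:
        raise StimulusError("amplitudes must be non-negative")
    if duration < 1.0 / frequency - 1e-12:
        raise StimulusError("duration must cover at least one period")
    n_frames = _check_timing(frequency, dt, duration)
    t = np.arange(n_frames) * dt
    phase = np.sin(2.0 * math.pi * frequency * t)  # (T,)

    x = h_amplitude * phase
    positions = np.zeros((n_frames, 3, 2))
    positions[:, 0] = np.stack([x, np.full_like(x, separation)], axis=1)
    positions[:, 1] = np.stack([x, v_amplitude * phase], axis=1)
    positions[:, 2] = np.stack([x, np.full_like(x, -separation)], axis=1)

    peak_v = 2.0 * math.pi * frequency * h_amplitude
    truth = np.tile([peak_v, 0.0], (3, 1))
    return Stimulus(
        positions=positions,
        dt=dt,
        labels=["outer", "middle", "outer"],
        truth=truth,
        meta={
            "generator": "johansson",
            "frequency": frequency,
            "h_amplitude": h_amplitude,
            "v_amplitude": v_amplitude,
            "dt": dt,
            "duration": duration,
            "separation": separation,
        },
    )


def generate_duncker(
    radius: float = 10.0,
    h_speed: float = 0.5,
    angular_speed: float | None = None,
    dt: float = 0.05,
    duration: float = 60.0,
    phase0_deg: float = 0.0,
) -> Stimulus:
    """Hub dot translating linearly plus a rim dot on a cycloid.

    The hub moves rightward at ``h_speed`` units/s; the rim sits at
    ``hub + radius*(cos(phi), sin(phi))`` with ``phi`` advancing at
    ``angular_speed`` (degrees per second), starting at the rightmost point
    of the wheel.  By default the wheel *rolls*: ``angular_speed =
    h_speed / radius`` (in rad/s), the kinematic constraint that makes the
    rim trace a cycloid of a rolling wheel.  The default duration covers
    about half a revolution of the rolling wheel.
    """
    if radius <= 0:
        raise StimulusError(f"radius must be positive, got {radius}")
    if angular_speed is None:
        angular_speed = math.degrees(h_speed / radius)
    n_frames = _check_timing(None, dt, duration)
    t = np.arange(n_frames) * dt
    hub = np.stack([h_speed * t, np.zeros_like(t)], axis=1)
    phi = np.radians(phase0_deg) + np.radians(angular_speed) * t
    rim = hub + radius * np.stack([np.cos(phi), np.sin(phi)], axis=1)

    positions = np.stack([hub, rim], axis=1)
    truth = np.tile([h_speed, 0.0], (2, 1))
    return Stimulus(
        positions=positions,
        dt=dt,
        labels=["hub", "rim"],
        truth=truth,
        meta={
            "generator": "duncker",
            "radius": radius,
            "h_speed": h_speed,
            "angular_speed": angular_speed,
            "dt": dt,
            "duration": duration,
        },
    )


def generate_rdk(
    n_dots: int = 1000,
    field_size: float | None = None,
    signal_ratio: float = 0.5,
    coherent_velocity: float = 0.01,
    noise_velocity: float = 0.01,
    dt: float = 0.05,
    duration: float = 25.0,
    seed: int = 0,
    noise_mode: str = "uniform_angle",
    density: float = 500.0,
) -> Stimulus:
    """Random dot kinematogram: coherent signal dots in a random-motion field.

    ``round(signal_ratio * n_dots)`` signal dots translate horizontally at
    ``coherent_velocity``; the remaining noise dots move at ``noise_velocity``
    with direction re-drawn per dot per frame.  ``noise_mode`` selects how
    noise directions are drawn:

    * ``"uniform_angle"`` (default): direction uniform on the circle.
    * ``"vertical_sign_flip"``: vertical motion with a random sign per frame.

    Initial positions are uniform over a square field whose side defaults to
    ``sqrt(n_dots / density)`` (dot density in dots per unit area).  Dots
    drift freely: at the study's speeds the total drift is a small fraction
    of the field side, so no boundary rule is applied and observed
    velocities stay exact.
    """
    if n_dots < 1:
        raise StimulusError(f"n_dots must be >= 1, got {n_dots}")
    if not 0.0 <= signal_ratio <= 1.0:
        raise StimulusError(f"signal_ratio must be in [0, 1], got {signal_ratio}")
    if noise_mode not in ("uniform_angle", "vertical_sign_flip"):
        raise StimulusError(f"unknown noise_mode {noise_mode!r}")
    n_frames = _check_timing(None, dt, duration)
    if field_size is None:
        field_size = math.sqrt(n_dots / density)

    rng = np.random.default_rng(seed)
    n_signal = int(round(signal_ratio * n_dots))
    n_noise = n_dots - n_signal

    start = rng.uniform(-field_size / 2.0, field_size / 2.0, size=(n_dots, 2))
    # Per-frame displacements: constant for signal dots, re-drawn for noise.
    disp = np.zeros((n_frames - 1, n_dots, 2))
    disp[:, :n_signal, 0] = coherent_velocity * dt
    if n_noise:
        if noise_mode == "uniform_angle":
            ang = rng.uniform(0.0, 2.0 * math.pi, size=(n_frames - 1, n_noise))
            step = noise_velocity * dt
            disp[:, n_signal:, 0] = step * np.cos(ang)
            disp[:, n_signal:, 1] = step * np.sin(ang)
        else:
            sign = rng.choice([-1.0, 1.0], size=(n_frames - 1, n_noise))
            disp[:, n_signal:, 1] = noise_velocity * dt * sign

    positions = np.concatenate(
        [start[None], start[None] + np.cumsum(disp, axis=0)], axis=0
    )
    labels = ["signal"] * n_signal + ["noise"] * n_noise
    truth = np.zeros((n_dots, 2))
    truth[:n_signal, 0] = coherent_velocity
    return Stimulus(
        positions=positions,
        dt=dt,
        labels=labels,
        truth=truth,
        meta={
            "generator": "rdk",
            "n_dots": n_dots,
            "field_size": field_size,
            "signal_ratio": signal_ratio,
            "coherent_velocity": coherent_velocity,
            "noise_velocity": noise_velocity,
            "dt": dt,
            "duration": duration,
            "seed": seed,
            "noise_mode": noise_mode,
        },
    )


# ---------------------------------------------------------------------------
# Trajectory file I/O
#
# UTF-8 comma-delimited table, header `frame,dot_id,x,y,label`, one row per
# dot per frame, frames contiguous from 0.  Metadata (dt, generator, seed,
# truth) is stored in `#`-prefixed comment lines before the header.


def write_stimulus(stimulus: Stimulus, path) -> None:
    """Write a stimulus to a delimited trajectory file (see module docs)."""
    meta = dict(stimulus.meta)
    meta["dt"] = stimulus.dt
    header = {
        "meta": meta,
        "labels": list(stimulus.labels),
        "truth": stimulus.truth.tolist(),
    }
    T, N, _ = stimulus.positions.shape
    frames = np.repeat(np.arange(T), N)
    dot_ids = np.tile(np.arange(N), T)
    df = pd.DataFrame(
        {
            "frame": frames,
            "dot_id": dot_ids,
            "x": stimulus.positions[:, :, 0].ravel(),
            "y": stimulus.positions[:, :, 1].ravel(),
            "label": np.tile(np.asarray(stimulus.labels, dtype=object), T),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pcmotion-stimulus v1\n")
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_stimulus(path) -> Stimulus:
    """Read a stimulus written by :func:`write_stimulus`.

    Raises :class:`StimulusParseError` on malformed rows, inconsistent dot
    counts per frame, or an empty table, naming the offending frame.
    """
    comments: list[str] = []
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                comments.append(line[1:].strip())
            else:
                body.write(line)
    body.seek(0)
    header: dict = {}
    for c in comments:
        if c.startswith("{"):
            try:
                header = json.loads(c)
            except json.JSONDecodeError as exc:
                raise StimulusParseError(f"bad metadata line: {exc}") from exc
    try:
        df = pd.read_csv(body)
    except pd.errors.EmptyDataError as exc:
        raise StimulusParseError("file contains no trajectory table") from exc
    required = {"frame", "dot_id", "x", "y", "label"}
    if not required.issubset(df.columns):
        raise StimulusParseError(
            f"missing columns: {sorted(required - set(df.columns))}"
        )
    if len(df) == 0:
        raise StimulusParseError("trajectory table is empty (header only)")
    if df[["frame", "dot_id", "x", "y"]].isna().any().any():
        bad = int(df[df[["x", "y"]].isna().any(axis=1)]["frame"].iloc[0])
        raise StimulusParseError(f"non-numeric or missing value at frame {bad}")

    frames = np.sort(df["frame"].unique())
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise StimulusParseError("frames are not contiguous from 0")
    counts = df.groupby("frame")["dot_id"].count()
    if counts.nunique() != 1:
        bad = int(counts[counts != counts.iloc[0]].index[0])
        raise StimulusParseError(
            f"inconsistent dot count at frame {bad}: "
            f"{int(counts.loc[bad])} vs {int(counts.iloc[0])}"
        )
    n_dots = int(counts.iloc[0])
    T = len(frames)
    df = df.sort_values(["frame", "dot_id"]).reset_index(drop=True)
    expected_ids = np.tile(np.arange(n_dots), T)
    if not np.array_equal(df["dot_id"].to_numpy(), expected_ids):
        raise StimulusParseError("dot_id values are not 0..N-1 in every frame")

    positions = df[["x", "y"]].to_numpy(float).reshape(T, n_dots, 2)
    labels = [str(v) for v in df["label"].to_numpy()[:n_dots]]

    meta = header.get("meta", {})
    dt = float(meta.get("dt", 0.0))
    if dt <= 0:
        raise StimulusParseError("metadata is missing a positive dt")
    truth = np.asarray(header.get("truth", np.zeros((n_dots, 2))), dtype=float)
    if truth.shape != (n_dots, 2):
        truth = np.zeros((n_dots, 2))
    if "labels" in header and len(header["labels"]) == n_dots:
        labels = [str(v) for v in header["labels"]]
    return Stimulus(positions=positions, dt=dt, labels=labels, truth=truth, meta=meta)
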