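"""Minimal plotting helpers for traces and sweeps."""

from __future__ import annotations

import numpy as np


def plot_sweep_line(sweep, ax=None, param: str | None = None):
    """Mean convergence time (+/- std) versus a sweep parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    param = param or sweep.param_names[0]
    s = sweep.summary.sort_values(param)
    ax.errorbar(s[param], s["mean_time_ms"], yerr=s["std_time_ms"], marker="o")
    ax.set_xlabel(param)
    ax.set_ylabel("convergence time [ms]")
    return ax


def plot_sweep_heatmap(sweep, ax=None):
    """Convergence-time matrix for a two-parameter sweep."""
    import matplotlib.pyplot as plt

    if len(sweep.param_names) != 2:
        raise ValueError("heatmap needs a two-parameter sweep")
    if ax is None:
        _, ax = plt.subplots()
    p0, p1 = sweep.param_names
    mat = sweep.summary.pivot(index=p0, columns=p1, values="mean_time_ms")
    im = ax.imshow(mat.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(np.arange(len(mat.columns)), [f"{v:g}" for v in mat.columns])
    ax.set_yticks(np.arange(len(mat.index)), [f"{v:g}" for v in mat.index])
    ax.set_xlabel(p1)
    ax.set_ylabel(p0)
    ax.figure.colorbar(im, ax=ax, label="convergence time [ms]")
    return ax
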