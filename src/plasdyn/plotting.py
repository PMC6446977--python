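"""Convenience plots over the CSV-shaped results (requires matplotlib)."""

from __future__ import annotations

from .dynamics import Trajectory
from .experiments import MainEffectCurve

__all__ = ["plot_trajectory", "plot_main_effect"]


def plot_trajectory(traj: Trajectory, ax=None, log_time: bool = False):
    """Compartment densities versus time for one run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.times, traj.F, label="plasmid-free (F)")
    ax.plot(traj.times, traj.P, label="non-adapted bearers (P)")
    ax.plot(traj.times, traj.A, label="adapted bearers (A)")
    if log_time:
        ax.set_xscale("symlog")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("relative density")
    ax.set_title(f"variant: {traj.params.variant.value}, upsilon = {traj.params.upsilon:g}")
    ax.legend()
    return ax


def plot_main_effect(curve: MainEffectCurve, ax=None):
    """Persistence percentage per bin for each model variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for variant in curve.table["variant"].unique():
        x, y = curve.curve(variant)
        ax.plot(x, y, marker="o", label=variant)
    ax.set_xlabel(f"{curve.parameter} ({curve.scale} scale)")
    ax.set_ylabel("plasmid persistence (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax
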