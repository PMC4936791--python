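"""Plotting helpers for experiment results."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_motion_benefit"]


def plot_motion_benefit(endpoint_table: pd.DataFrame, field_label: str = "1.5T",
                        ax_pair=None):
    """Scatter the per-case tracking benefit against tumor motion, with the
    OLS fit lines: mean lung dose (left) and integral deposited energy
    (right), tracked minus conventional at the given field strength."""
    import matplotlib.pyplot as plt

    from .stats_compare import motion_regression

    df = endpoint_table.reset_index()
    wide = df.pivot(index="case", columns="arm")
    arm_t, arm_c = f"track_{field_label}", f"conv_{field_label}"
    motion = wide[("motion_mm", arm_t)].to_numpy()
    if ax_pair is None:
        fig, ax_pair = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    else:
        fig = ax_pair[0].figure
    for ax, ep, label in zip(
        ax_pair,
        ("lung_mean", "integral_energy_j"),
        ("mean lung dose difference (Gy)", "integral energy difference (J)"),
    ):
        diff = (wide[(ep, arm_t)] - wide[(ep, arm_c)]).to_numpy()
        ax.scatter(motion, diff, color="tab:blue")
        if motion.size >= 3 and motion.std() > 0:
            fit = motion_regression(motion, diff, ep)
            xs = np.linspace(motion.min(), motion.max(), 50)
            ax.plot(xs, fit.intercept + fit.slope * xs, "k-",
                    label=f"r = {fit.r:.2f}")
            ax.legend(frameon=False)
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel("peak-to-peak tumor motion (mm)")
        ax.set_ylabel(label)
    fig.suptitle(f"tracked - conventional at {field_label}")
    fig.tight_layout()
    return fig
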