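"""Small-multiple trajectory panels for the simulated clusters."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .model_core import VARIABLES  # noqa: E402
from .simulate import Trajectory  # noqa: E402

__all__ = ["plot_trajectories"]

_LABELS = {
    "M_N": "naive macrophages", "M": "macrophages", "T_N": "naive T cells",
    "T_h": "helper T cells", "T_r": "regulatory T cells",
    "T_c": "cytotoxic cells", "D_N": "naive dendritic cells",
    "D": "dendritic cells", "C": "cancer cells", "N": "necrotic cells",
    "I_g": "IFN-$\\gamma$", "mu1": "$\\mu_1$ (TGF-$\\beta$/IL-4/10/13)",
    "mu2": "$\\mu_2$ (IL-6/IL-17)", "H": "HMGB1",
}


def plot_trajectories(trajectories: Mapping[int, Trajectory],
                      path: str | None = None):
    """One panel per model variable, one line per cluster.

    Dimensionless trajectories are plotted as ratios to the cluster
    steady state (equilibria at 1).  Returns the matplotlib figure;
    writes it to ``path`` when given.
    """
    fig, axes = plt.subplots(4, 4, figsize=(14, 10), sharex=True)
    for ax, name in zip(axes.ravel(), VARIABLES):
        for k in sorted(trajectories):
            traj = trajectories[k]
            ax.plot(traj.t, traj.variable(name), label=f"cluster {k}")
        ax.set_title(_LABELS.get(name, name), fontsize=9)
        ax.tick_params(labelsize=8)
    for ax in axes.ravel()[len(VARIABLES):]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("time [days]", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
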