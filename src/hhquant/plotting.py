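"""Overlay plot of the profile decomposition."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .datatypes import DecompositionResult


def plot_decomposition(result: DecompositionResult, path=None):
    """WT, resistant-average and no-reduction curves with inhibition guide lines."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(result.grid, result.c_wt, color="black", label="Ci-155 (WT)")
    ax.plot(result.grid, result.c_resistant_avg, color="gray", label="Ci-155 (resistant avg)")
    ax.plot(result.grid, result.c_nored, color="tab:blue", label="no-reduction curve")
    for x, ls, lab in (
        (result.x_first_inh, ":", "first inhibited"),
        (result.x_half_inh, "--", "50% inhibited"),
        (result.x_full_inh, "-", "fully inhibited"),
    ):
        if x == x:  # skip NaN
            ax.axvline(x, color="tab:blue", linestyle=ls, alpha=0.6, label=lab)
    ax.set_xlabel("AP position (um, boundary at 0)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
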