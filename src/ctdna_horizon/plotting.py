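"""Report plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def paired_maf_plot(outcomes, path: str | Path) -> None:
    """Paired Early vs Very Early MAF plot for the positive participants.

    One line per participant connecting the Early and Very Early mean MAFs
    (log scale); Very Early samples without detectable mutations are drawn
    at the floor with an open marker.
    """
    positives = [o for o in outcomes if o.early_positive and o.early_maf]
    fig, ax = plt.subplots(figsize=(5, 4))
    floor = 1e-5
    for o in positives:
        early = 100.0 * o.early_maf
        if o.very_early_maf:
            ve = 100.0 * o.very_early_maf
            ax.plot([0, 1], [early, ve], "o-", color="tab:blue", alpha=0.8)
        else:
            ax.plot([0, 1], [early, 100 * floor], "o--", color="tab:gray", alpha=0.6,
                    markerfacecolor="none")
        ax.annotate(o.pid, (0, early), textcoords="offset points",
                    xytext=(-8, 0), ha="right", fontsize=7)
    ax.set_yscale("log")
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["Early", "Very Early"])
    ax.set_xlim(-0.5, 1.5)
    ax.set_ylabel("Mean MAF (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
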