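"""Swimmer-style trajectory plot.

One row per tracked variant, time in months before MM diagnosis on the x
axis (MM at the right edge).  A filled marker sized by VAF marks a
significant detection; an open marker marks a tested-but-undetected
timepoint.  Variants of the same patient are grouped and labelled.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .tracking import Trajectory

__all__ = ["plot_trajectories"]


def plot_trajectories(trajectories: Sequence[Trajectory], ax: Optional[plt.Axes] = None):
    if ax is None:
        _, ax = plt.subplots(
            figsize=(8, max(2.0, 0.35 * max(len(trajectories), 1)))
        )
    ordered = sorted(trajectories, key=lambda t: (t.patient_id, t.gene))
    for row, traj in enumerate(ordered):
        months = [tp.months_before_mm for tp in traj.timepoints]
        ax.plot(months, [row] * len(months), color="0.8", lw=0.8, zorder=1)
        for tp in traj.timepoints:
            if tp.vaf is None:
                ax.scatter(
                    tp.months_before_mm, row, marker="x", s=18, color="0.6", zorder=2
                )
            elif tp.detected:
                size = 20 + 380 * min(tp.vaf, 0.5)
                ax.scatter(
                    tp.months_before_mm, row, s=size, color="black", zorder=3
                )
            else:
                ax.scatter(
                    tp.months_before_mm,
                    row,
                    s=28,
                    facecolors="none",
                    edgecolors="black",
                    zorder=3,
                )
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([f"{t.patient_id} {t.gene}" for t in ordered], fontsize=7)
    ax.set_xlabel("months before MM diagnosis")
    ax.invert_xaxis()
    ax.set_title("Variant detection across serial samples")
    ax.figure.tight_layout()
    return ax.figure
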