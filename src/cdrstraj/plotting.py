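"""Basic per-item severity trajectory plot."""

from __future__ import annotations

import numpy as np

from .cohort import Cohort
from .mixture import BaselineMixture, assign_baseline_stratum
from .scale import CDRS_ITEMS, VISITS


def plot_symptom_trajectories(
    cohort: Cohort,
    item_id: int,
    paths=None,
    mixture: BaselineMixture | None = None,
    ax=None,
):
    """Mean +/- 95% CI of one item's severity across the three visits,
    optionally split by symptom dynamic path."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(3)

    def _series(mask):
        means, half = [], []
        for v in VISITS:
            vals = cohort.items(v)[mask, item_id - 1]
            means.append(vals.mean())
            half.append(1.96 * vals.std(ddof=1) / np.sqrt(max(1, vals.size)))
        return np.array(means), np.array(half)

    if paths and mixture is not None:
        a = np.array(
            [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
        )
        b = cohort.followup_strata("mid")
        c = cohort.followup_strata("end")
        for p in paths:
            mask = (a == p.baseline) & (b == p.mid) & (c == p.end)
            if mask.sum() < 3:
                continue
            m, h = _series(mask)
            ax.plot(x, m, marker="o", label=f"{p.baseline}->{p.mid}->{p.end}")
            ax.fill_between(x, m - h, m + h, alpha=0.2)
        ax.legend(fontsize=7)
    else:
        m, h = _series(np.ones(len(cohort), dtype=bool))
        ax.plot(x, m, marker="o", color="C0")
        ax.fill_between(x, m - h, m + h, alpha=0.2, color="C0")

    ax.set_xticks(x, ["baseline", "4-6 wk", "10-12 wk"])
    ax.set_ylabel("severity")
    ax.set_title(CDRS_ITEMS[item_id - 1].label)
    return ax
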