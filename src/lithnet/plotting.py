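"""Figure helpers: null-distribution boxplots and bootstrap bands.

Thin matplotlib wrappers over the result objects; aesthetics are left
to the caller.  Each function returns the Axes it drew on.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .sampling import BootstrapReport
from .smallworld import SmallWorldResult

__all__ = ["plot_null_distributions", "plot_bootstrap_bands"]


def plot_null_distributions(
    results: Sequence[SmallWorldResult], statistic: str = "cc", ax=None
):
    """Boxplots of the null ensembles with the observed value overlaid.

    ``statistic`` is ``'cc'`` (clustering) or ``'apl'``; one box per
    bin, the observed value as a dashed red line segment on each box.
    """
    import matplotlib.pyplot as plt

    if statistic not in ("cc", "apl"):
        raise ValueError("statistic must be 'cc' or 'apl'")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    data, labels, observed = [], [], []
    for r in results:
        vals = r.null_cc if statistic == "cc" else r.null_apl
        vals = np.asarray(vals, dtype=float)
        data.append(vals[np.isfinite(vals)])
        labels.append(r.bin_label)
        observed.append(r.observed_cc if statistic == "cc" else r.observed_apl)
    ax.boxplot(data, tick_labels=labels)
    for i, obs in enumerate(observed, start=1):
        if np.isfinite(obs):
            ax.plot([i - 0.35, i + 0.35], [obs, obs], "r--")
    ax.set_ylabel("clustering coefficient" if statistic == "cc" else "average path length")
    ax.set_xlabel("time bin (cal BP)")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_bootstrap_bands(report: BootstrapReport, ax=None):
    """Observed weighted degree per context against its bootstrap band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 * len(report.observed_degree) + 2, 4))
    x = np.arange(len(report.observed_degree))
    ax.fill_between(x, report.ci_low.values, report.ci_high.values,
                    alpha=0.3, label="95% bootstrap band")
    ax.plot(x, report.observed_degree.values, "o-", label="observed")
    ax.set_xticks(x)
    ax.set_xticklabels(report.observed_degree.index, rotation=45, ha="right")
    ax.set_ylabel("weighted degree")
    ax.set_title(f"bin {report.bin_label}")
    ax.legend()
    return ax
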