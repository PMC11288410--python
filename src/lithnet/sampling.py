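"""Bootstrap assessment of sampling error in similarity networks.

Archaeological assemblages are samples: the handful of artefacts
recovered from a context stands in for the population of artefacts once
in use there.  To ask how fragile the network structure is to that
sampling, each bin is resampled: every context's type counts are
redrawn from a multinomial with that context's observed type
proportions and its observed sample size (sample sizes are held
constant; only composition fluctuates).  Each replicate is re-binarised
and rebuilt into a Jaccard network, and the distribution of node and
structural metrics across replicates quantifies the sampling noise.

The report summarises, per context, the 95% band of its weighted degree
(the sum of its Jaccard similarities — 'strength'), whether its
observed value lies inside the band, and how often its degree rank
stays within +/-1 of the observed rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .similarity import BinAssemblage, jaccard_matrix

__all__ = ["BootstrapReport", "bootstrap_bin", "resample_counts"]


def resample_counts(freq: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One bootstrap replicate of a contexts x types count table.

    Each row is redrawn from ``Multinomial(n_row, p_row)`` with the
    row's observed proportions; row sums are conserved exactly.
    """
    counts = freq.to_numpy()
    n_per = counts.sum(axis=1)
    if (n_per < 1).any():
        raise ValueError("every context must have at least one record")
    probs = counts / n_per[:, None]
    resampled = np.vstack(
        [rng.multinomial(int(n), p) for n, p in zip(n_per, probs)]
    )
    return pd.DataFrame(resampled, index=freq.index, columns=freq.columns)


@dataclass
class BootstrapReport:
    """Replicate distributions of node and structural metrics for a bin."""

    bin_label: str
    replicates: int
    seed: int | None
    observed_degree: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    rank_stability: pd.Series  # fraction of replicates with rank within +/-1
    fraction_within_ci: float
    metric_draws: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        """Long per-context summary (one row per node)."""
        return pd.DataFrame(
            {
                "bin": self.bin_label,
                "context": self.observed_degree.index,
                "observed_degree": self.observed_degree.values,
                "ci_low": self.ci_low.values,
                "ci_high": self.ci_high.values,
                "rank_stability": self.rank_stability.values,
            }
        )


def _strength(J: pd.DataFrame) -> np.ndarray:
    """Weighted degree: row sums of the similarity matrix, diagonal off."""
    a = J.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def bootstrap_bin(
    assemblage: BinAssemblage,
    replicates: int = 1000,
    seed: int | None = None,
    rank_tol: int = 1,
    ci: float = 0.95,
) -> BootstrapReport:
    """Multinomial bootstrap of one bin's similarity network.

    Each replicate redraws every context's type counts from
    ``Multinomial(n_context, p_context)`` with the observed proportions,
    so per-context sample sizes are conserved exactly.  A context with a
    single observed type is degenerate: its replicates never vary.
    """
    freq = assemblage.freq
    if len(freq) < 2:
        raise ValueError("bootstrap needs a bin with at least two contexts")
    contexts = list(freq.index)

    observed_J = jaccard_matrix(assemblage.binary)
    observed_deg = _strength(observed_J)
    observed_rank = rankdata(-observed_deg, method="average")

    rng = np.random.default_rng(seed)
    deg_draws = np.empty((replicates, len(contexts)))
    rank_hits = np.zeros(len(contexts))
    metric_rows = []
    for k in range(replicates):
        resampled = resample_counts(freq, rng)
        J = jaccard_matrix((resampled >= 1).astype(int))
        deg = _strength(J)
        deg_draws[k] = deg
        rank_hits += np.abs(rankdata(-deg, method="average") - observed_rank) <= rank_tol
        a = J.to_numpy()
        n = len(a)
        off = a[np.triu_indices(n, k=1)]
        metric_rows.append(
            {"replicate": k, "mean_similarity": float(off.mean()),
             "edge_fraction": float((off > 0).mean())}
        )

    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(deg_draws, alpha, axis=0)
    hi = np.quantile(deg_draws, 1.0 - alpha, axis=0)
    within = (observed_deg >= lo) & (observed_deg <= hi)
    return BootstrapReport(
        bin_label=assemblage.bin_label,
        replicates=replicates,
        seed=seed,
        observed_degree=pd.Series(observed_deg, index=contexts),
        ci_low=pd.Series(lo, index=contexts),
        ci_high=pd.Series(hi, index=contexts),
        rank_stability=pd.Series(rank_hits / replicates, index=contexts),
        fraction_within_ci=float(within.mean()),
        metric_draws=pd.DataFrame(metric_rows).set_index("replicate"),
    )
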