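"""Distributional and positional analysis of 1-D inter-bundle distance sequences.

A :class:`DistanceSequence` is an ordered list of centre-to-centre spacings
measured along a cortical traverse; order encodes position, so gradients of
spacing across the cortical sheet can be detected by scanning consecutive
groups.  The module computes the moment summaries and normality screens
used for between-block comparisons, nonparametric two-sample and k-sample
tests, anchored histograms, and the sequential-groups-of-100 scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class DistanceSequence:
    """Ordered inter-bundle distances (um) along a layer-V traverse."""

    values: np.ndarray
    block: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size and np.any(v <= 0):
            raise ValueError("inter-bundle distances must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class DistributionSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    ks_statistic: float
    ks_p: float


@dataclass
class GroupScan:
    group_size: int
    means: np.ndarray
    sds: np.ndarray
    medians: np.ndarray
    p_values: np.ndarray
    test_names: list[str]
    n_dropped: int


def summarize(seq: DistanceSequence) -> DistributionSummary:
    """Moment summary plus a Kolmogorov-Smirnov normality screen.

    SD uses the n-1 denominator; skewness and excess kurtosis are the
    bias-adjusted standardized third/fourth moments (normal = 0).  The KS
    statistic is computed against a Gaussian with the sample's own mean/SD
    and its p-value from the asymptotic KS law; estimating the parameters
    from the same sample inflates this p-value (no Lilliefors correction),
    matching how such tables are conventionally reported.
    """
    if seq.n < 8:
        raise ValueError(f"summary needs n >= 8, got {seq.n}")
    v = seq.values
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate input: all distances identical (sd = 0)")
    ks = stats.kstest(v, "norm", args=(v.mean(), sd))
    return DistributionSummary(
        n=seq.n,
        mean=float(v.mean()),
        sd=sd,
        skewness=float(stats.skew(v, bias=False)),
        excess_kurtosis=float(stats.kurtosis(v, fisher=True, bias=False)),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def bin_histogram(seq: DistanceSequence, bin_width: float):
    """Normalised frequencies in bins [0, w), [w, 2w), ... anchored at zero.

    Returns ``(bin_edges, freq)``; frequencies sum to 1 and reconstruct the
    raw counts when multiplied by n.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = seq.values
    n_bins = int(np.floor(v.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    idx = np.minimum((v // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts / v.size


def compare_groups(
    a: DistanceSequence, b: DistanceSequence, method: str = "mann_whitney"
) -> float:
    """Two-sided two-sample p-value (Mann-Whitney by default, or unpaired t).

    Mann-Whitney uses exact enumeration when both samples have n <= 20 and
    no ties, and the tie-corrected normal approximation otherwise.
    """
    if a.n < 8 or b.n < 8:
        raise ValueError("each sample needs n >= 8")
    pooled = np.concatenate([a.values, b.values])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate comparison: all values tied")
    if method == "mann_whitney":
        small = a.n <= 20 and b.n <= 20
        has_ties = np.unique(pooled).size < pooled.size
        mw_method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a.values, b.values, alternative="two-sided", method=mw_method
        )
        return float(res.pvalue)
    if method == "t_test":
        return float(stats.ttest_ind(a.values, b.values).pvalue)
    raise ValueError("method must be 'mann_whitney' or 't_test'")


def kruskal_wallis(seqs: list[DistanceSequence]) -> float:
    """Kruskal-Wallis H test (tie-corrected, chi-square p on k-1 df).

    With exactly two groups the problem is a two-sample one and the
    Mann-Whitney result from :func:`compare_groups` is returned instead.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 groups")
    for s in seqs:
        if s.n < 8:
            raise ValueError("each group needs n >= 8")
    if len(seqs) == 2:
        return compare_groups(seqs[0], seqs[1], method="mann_whitney")
    return float(stats.kruskal(*[s.values for s in seqs]).pvalue)


def sequential_groups(
    seq: DistanceSequence, group_size: int = 100, method: str = "mann_whitney"
) -> GroupScan:
    """Scan consecutive non-overlapping groups along the traverse.

    Per-group mean/SD/median in traverse order, plus a p-value between each
    adjacent pair.  ``method`` is ``mann_whitney``, ``t_test``, or ``auto``
    (t test when both groups of a pair pass the KS normality screen at
    p > 0.05, Mann-Whitney otherwise).  A trailing remainder shorter than
    ``group_size`` is dropped.
    """
    if group_size < 8:
        raise ValueError("group_size must be >= 8")
    n_groups = seq.n // group_size
    if n_groups < 2:
        raise ValueError(
            f"need at least {2 * group_size} values for a scan with "
            f"group_size={group_size}, got {seq.n}"
        )
    groups = [
        seq.values[i * group_size : (i + 1) * group_size] for i in range(n_groups)
    ]
    n_dropped = seq.n - n_groups * group_size
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    medians = np.array([np.median(g) for g in groups])
    p_values = np.empty(n_groups - 1)
    test_names = []
    for i in range(n_groups - 1):
        a = DistanceSequence(groups[i])
        b = DistanceSequence(groups[i + 1])
        use = method
        if method == "auto":
            normal = all(
                stats.kstest(
                    g, "norm", args=(g.mean(), g.std(ddof=1))
                ).pvalue > 0.05
                for g in (groups[i], groups[i + 1])
            )
            use = "t_test" if normal else "mann_whitney"
        p_values[i] = compare_groups(a, b, method=use)
        test_names.append(use)
    return GroupScan(
        group_size=group_size,
        means=means,
        sds=sds,
        medians=medians,
        p_values=p_values,
        test_names=test_names,
        n_dropped=n_dropped,
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; scans report raw p by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
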