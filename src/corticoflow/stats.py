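"""Hierarchical bootstrap estimation and hypothesis tests.

Nested measurements (values within sessions or onsets, within mice) are
resampled in two stages: mice with replacement, then the level-2 units of
each selected mouse with replacement.  The mean of each of ``n_boot``
resamples forms the bootstrap distribution; the confidence interval is
the central quantile interval, and one-sided p-values are the proportion
of bootstrap means on the null side of zero (replicates exactly at zero
are split evenly between the tails).  The second-stage resample size
equals the number of level-2 units the selected mouse contributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class NestedSample:
    """Measurements tagged with mouse (level 1) and session/onset (level 2)."""

    values: np.ndarray
    level1: np.ndarray  # mouse label per value
    level2: np.ndarray  # session-or-onset label per value

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.level1 = np.asarray(self.level1)
        self.level2 = np.asarray(self.level2)
        if not (self.values.shape == self.level1.shape == self.level2.shape):
            raise ValueError("values and labels must have identical shapes")
        if self.values.size == 0:
            raise ValueError("empty sample")


@dataclass
class BootstrapEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci: float
    p_greater: float  # proportion of bootstrap means > 0
    p_less: float     # proportion of bootstrap means < 0
    seed: int | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)

    def to_jsonable(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_boot": self.n_boot,
                "ci": self.ci, "p_greater": self.p_greater,
                "p_less": self.p_less, "seed": self.seed}


def _tail_proportions(reps: np.ndarray) -> tuple[float, float]:
    n = reps.size
    greater = float(np.count_nonzero(reps > 0))
    less = float(np.count_nonzero(reps < 0))
    ties = n - greater - less
    return (greater + 0.5 * ties) / n, (less + 0.5 * ties) / n


def _finish(reps: np.ndarray, point: float, ci: float, n_boot: int,
            seed: int | None) -> BootstrapEstimate:
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    p_greater, p_less = _tail_proportions(reps)
    return BootstrapEstimate(point=float(point), ci_low=float(lo),
                             ci_high=float(hi), n_boot=n_boot, ci=ci,
                             p_greater=p_greater, p_less=p_less, seed=seed,
                             replicates=reps)


def boot(values: np.ndarray, n_boot: int = 10000, ci: float = 0.90,
         rng: np.random.Generator | None = None,
         seed: int | None = None) -> BootstrapEstimate:
    """Plain (non-nested) bootstrap of the mean: resample data points."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    reps = values[idx].mean(axis=1)
    return _finish(reps, values.mean(), ci, n_boot, seed)


def hboot_replicates(sample: NestedSample, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Bootstrap-mean replicates from two-stage (mice, then level-2 units)
    resampling.  Fully vectorised over replicates."""
    mice = np.unique(sample.level1)
    n_mice = mice.size
    # per mouse: the mean and size of each level-2 unit
    unit_means: list[np.ndarray] = []
    unit_sizes: list[np.ndarray] = []
    for m in mice:
        sel = sample.level1 == m
        units = np.unique(sample.level2[sel])
        means = np.array([sample.values[sel & (sample.level2 == u)].mean()
                          for u in units])
        sizes = np.array([np.count_nonzero(sel & (sample.level2 == u))
                          for u in units], dtype=float)
        unit_means.append(means)
        unit_sizes.append(sizes)
    n_units = np.array([u.size for u in unit_means])
    max_u = int(n_units.max())
    pad_means = np.zeros((n_mice, max_u))
    pad_sizes = np.zeros((n_mice, max_u))
    for i, (mm, ss) in enumerate(zip(unit_means, unit_sizes)):
        pad_means[i, :mm.size] = mm
        pad_sizes[i, :mm.size] = ss

    reps = np.empty(n_boot)
    chunk = max(1, int(5e6 // max(n_mice * max_u, 1)))
    for start in range(0, n_boot, chunk):
        nb = min(chunk, n_boot - start)
        mouse_idx = rng.integers(0, n_mice, size=(nb, n_mice))
        k = n_units[mouse_idx]  # units contributed by each selected mouse
        u = rng.random((nb, n_mice, max_u))
        unit_idx = np.minimum((u * k[..., None]).astype(np.intp),
                              (k - 1)[..., None])
        sel_means = pad_means[mouse_idx[..., None], unit_idx]
        sel_sizes = pad_sizes[mouse_idx[..., None], unit_idx]
        valid = np.arange(max_u)[None, None, :] < k[..., None]
        sel_sizes = np.where(valid, sel_sizes, 0.0)
        reps[start:start + nb] = ((sel_means * sel_sizes).sum((1, 2))
                                  / sel_sizes.sum((1, 2)))
    return reps


def hboot(sample: NestedSample, n_boot: int = 10000, ci: float = 0.90,
          rng: np.random.Generator | None = None,
          seed: int | None = None) -> BootstrapEstimate:
    """Hierarchical bootstrap of the mean of a nested sample."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    reps = hboot_replicates(sample, n_boot, rng)
    return _finish(reps, sample.values.mean(), ci, n_boot, seed)


def _onset_count_matrix(mouse_labels: np.ndarray, n_boot: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n_onsets) resampling counts for a two-stage resample of
    onsets nested in mice; one row defines one coherent replicate."""
    mouse_labels = np.asarray(mouse_labels)
    mice = np.unique(mouse_labels)
    n_mice = mice.size
    onset_idx = [np.flatnonzero(mouse_labels == m) for m in mice]
    n_per = np.array([ix.size for ix in onset_idx])
    counts = np.zeros((n_boot, mouse_labels.size), dtype=np.float64)
    mouse_draws = rng.integers(0, n_mice, size=(n_boot, n_mice))
    times_chosen = np.zeros((n_boot, n_mice), dtype=np.intp)
    for b in range(n_boot):
        np.add.at(times_chosen[b], mouse_draws[b], 1)
    for mi in range(n_mice):
        ix = onset_idx[mi]
        total = times_chosen[:, mi] * n_per[mi]
        for b in np.flatnonzero(total):
            draws = rng.integers(0, n_per[mi], size=total[b])
            np.add.at(counts[b], ix[draws], 1)
    return counts


def hboot_timecourse(
    data: np.ndarray,
    mouse_labels: Sequence,
    n_boot: int = 1000,
    ci: float = 0.90,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    share_indices: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin hierarchical-bootstrap band for onset-aligned data.

    ``data`` is (n_onsets, ...) — typically (n_onsets, n_roi, n_bins).
    Returns (mean, ci_low, ci_high), each with the trailing shape of
    ``data``.  With ``share_indices`` one resample of (mice, onsets) is
    applied to every bin of a replicate so the band is trace-coherent;
    with it off, every bin is resampled independently.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] == 0:
        raise ValueError("no onsets")
    mouse_labels = np.asarray(mouse_labels)
    if mouse_labels.shape[0] != data.shape[0]:
        raise ValueError("one mouse label per onset required")
    rng = rng if rng is not None else np.random.default_rng(seed)
    flat = data.reshape(data.shape[0], -1)
    mean = flat.mean(axis=0)
    if share_indices:
        counts = _onset_count_matrix(mouse_labels, n_boot, rng)
        reps = (counts @ flat) / counts.sum(axis=1, keepdims=True)
    else:
        reps = np.empty((n_boot, flat.shape[1]))
        for j in range(flat.shape[1]):
            counts = _onset_count_matrix(mouse_labels, n_boot, rng)
            reps[:, j] = (counts @ flat[:, j]) / counts.sum(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha], axis=0)
    shape = data.shape[1:]
    return mean.reshape(shape), lo.reshape(shape), hi.reshape(shape)


# ---------------------------------------------------------------------------
# classical tests


def fwe_adjust(alpha: float, m: int) -> float:
    """Family-wise adjusted significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def _exact_ranksum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided permutation-exact p for the rank sum of the first group.

    Enumerates the distribution of the sum of ``n_x`` midranks drawn from
    the pooled midranks via a subset-sum count (ties handled exactly).
    p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    # midranks are multiples of 1/2: double to integers
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n_x + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        upper = min(n_x, ranks.size)
        for k in range(upper - 1, -1, -1):
            dp[k + 1, r:] += dp[k, :total + 1 - r]
    dist = dp[n_x]
    n_comb = dist.sum()
    w2 = 2 * w_obs
    sums = np.arange(total + 1)
    p_le = dist[sums <= w2 + 1e-9].sum() / n_comb
    p_ge = dist[sums >= w2 - 1e-9].sum() / n_comb
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    Returns (W, p) where W is the rank sum of ``x`` in the pooled sample.
    Groups of at most ``exact_max_n`` values each are tested by exact
    enumeration of the permutation distribution; larger groups use the
    tie-corrected normal approximation (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:x.size].sum())
    n, m = x.size, y.size
    if n <= exact_max_n and m <= exact_max_n:
        return w, _exact_ranksum_p(ranks, n, w)
    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())
                     / (big_n * (big_n - 1)))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    return w, float(2.0 * sps.norm.sf(abs(z)))


def oneway_anova_then_boot(
    groups: Mapping[str, Sequence[float]],
    n_boot: int = 10000,
    ci: float = 0.90,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[float, float, dict[str, BootstrapEstimate]]:
    """Classical one-way ANOVA followed by per-group bootstrap p-values.

    Returns (F, p_anova, {group: BootstrapEstimate vs 0}).  Degenerate
    inputs use documented conventions: no variance anywhere -> F = 0,
    p = 1; zero within-group variance with real between-group differences
    -> F = +inf, p = 0.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb = len(arrays) - 1
    dfw = all_vals.size - len(arrays)
    if ssw == 0 and ssb == 0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f_stat, dfb, dfw))
    rng = rng if rng is not None else np.random.default_rng(seed)
    per_group = {g: boot(a, n_boot=n_boot, ci=ci, rng=rng)
                 for g, a in zip(labels, arrays)}
    return float(f_stat), p, per_group
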