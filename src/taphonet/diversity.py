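"""Sampling-effort diagnostics: richness estimators and rarefaction.

Quadrat excavations of lake deposits pool a few hyper-abundant aquatic
taxa with a long tail of rare terrestrial ones, so observed richness
``S_obs`` alone understates how much diversity remains unsampled. This
module provides the nonparametric estimators Chao1 and ACE, which lean
on the counts of rare taxa (singletons F1, doubletons F2, and the whole
rare tail respectively), individual-based rarefaction curves for any of
the three estimators, logarithmic curve fits, and the slope of the
fitted curve at a chosen sample size as a stopping criterion.

Chao1 = S_obs + F1(F1-1) / (2 F2), replaced by the bias-corrected form
S_obs + F1(F1-1) / (2 (F2+1)) when F2 = 0 so the estimate stays finite.

ACE splits taxa at a rare-abundance threshold (default 10 individuals):
S_ace = S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2, with sample
coverage C_ace = 1 - F1/N_rare and gamma^2 the squared coefficient of
variation of the rare counts, floored at 0.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CountVector",
    "RarefactionCurve",
    "LogFit",
    "sobs",
    "chao1",
    "ace",
    "rarefy",
    "expected_sobs",
    "fit_log",
    "slope_at",
]


@dataclass(frozen=True)
class CountVector:
    """Pooled abundances, one entry per OTU (zeros allowed)."""

    counts: tuple[int, ...]

    def __init__(self, counts: Sequence[int]):
        arr = [int(c) for c in counts]
        if any(c < 0 for c in arr):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", tuple(arr))

    @property
    def n_individuals(self) -> int:
        return sum(self.counts)

    def frequency_counts(self) -> Counter[int]:
        """F_i: number of OTUs represented by exactly i individuals."""
        return Counter(c for c in self.counts if c > 0)

    def f(self, i: int) -> int:
        return self.frequency_counts()[i]


def _as_counts(v: CountVector | Sequence[int]) -> CountVector:
    return v if isinstance(v, CountVector) else CountVector(v)


def sobs(v: CountVector | Sequence[int]) -> int:
    """Observed richness: number of OTUs with at least one individual."""
    return sum(1 for c in _as_counts(v).counts if c > 0)


def chao1(v: CountVector | Sequence[int]) -> float:
    """Chao1 richness estimate (bias-corrected when no doubletons).

    Always >= sobs; equals sobs when there are no singletons.
    """
    v = _as_counts(v)
    s = sobs(v)
    freq = v.frequency_counts()
    f1, f2 = freq[1], freq[2]
    if f2 > 0:
        return s + f1 * (f1 - 1) / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0  # bias-corrected: /(2*(F2+1)) with F2=0


def ace(v: CountVector | Sequence[int], rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    OTUs with more than ``rare_threshold`` individuals are "abundant";
    the rest form the rare group whose sample coverage and coefficient
    of variation drive the correction. Degenerate rare groups (no rare
    OTUs, N_rare <= 1, or zero coverage) fall back to :func:`chao1`.
    """
    if rare_threshold < 1:
        raise ValueError("rare_threshold must be >= 1")
    v = _as_counts(v)
    freq = v.frequency_counts()
    s_abund = sum(1 for c in v.counts if c > rare_threshold)
    s_rare = sum(1 for c in v.counts if 0 < c <= rare_threshold)
    n_rare = sum(c for c in v.counts if 0 < c <= rare_threshold)
    f1 = freq[1]
    if s_rare == 0 or n_rare <= 1:
        return chao1(v)
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        return chao1(v)
    ssq = sum(i * (i - 1) * freq[i] for i in range(1, rare_threshold + 1))
    gamma2 = max((s_rare / c_ace) * ssq / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


_ESTIMATORS: dict[str, Callable[..., float]] = {
    "sobs": lambda v, **kw: float(sobs(v)),
    "chao1": lambda v, **kw: chao1(v),
    "ace": lambda v, **kw: ace(v, **kw),
}


@dataclass
class RarefactionCurve:
    """Estimator values at increasing subsample sizes.

    ``points`` holds (n, mean, sd) triples; n runs over multiples of
    ``step`` up to the pool size N, with N itself always included as the
    final point.
    """

    estimator: str
    points: list[tuple[int, float, float]]
    step: int
    reps: int
    seed: int | None

    @property
    def n_values(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def sds(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


def _pool_from_counts(counts: Sequence[int]) -> np.ndarray:
    """Individual pool: one entry per specimen, labelled by OTU index."""
    return np.repeat(np.arange(len(counts)), counts)




def rarefy(
    v: CountVector | Sequence[int],
    estimator: str = "sobs",
    step: int = 50,
    reps: int = 100,
    seed: int | None = 0,
    *,
    rare_threshold: int = 10,
    exhaustive: bool = False,
) -> RarefactionCurve:
    """Individual-based rarefaction of a richness estimator.

    Draws ``reps`` subsamples of each size n (without replacement, from
    the pool of individuals implied by the counts) and records the mean
    and across-replicate sd of the estimator. Within one replicate the
    subsamples are nested (prefixes of a single shuffle of the pool), so
    each size-n subsample is uniform over all size-n subsets but one
    full shuffle serves the whole curve. With ``exhaustive=True`` every
    subsample of each size is enumerated instead (only sensible for
    tiny pools; the mean is then exact).
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {sorted(_ESTIMATORS)}")
    if step < 1 or reps < 1:
        raise ValueError("step and reps must be >= 1")
    v = _as_counts(v)
    n_total = v.n_individuals
    if n_total == 0:
        raise ValueError("cannot rarefy an empty sample")
    fn = _ESTIMATORS[estimator]
    kw = {"rare_threshold": rare_threshold} if estimator == "ace" else {}

    sizes = list(range(step, n_total + 1, step))
    if not sizes or sizes[-1] != n_total:
        sizes.append(n_total)

    pool = _pool_from_counts(v.counts)
    n_taxa = len(v.counts)
    rng = np.random.default_rng(seed)
    if exhaustive:
        points = []
        for n in sizes:
            vals = np.array([
                fn(CountVector(np.bincount(list(combo), minlength=n_taxa)), **kw)
                for combo in itertools.combinations(pool, n)
            ])
            points.append((n, float(vals.mean()), float(vals.std(ddof=0))))
        return RarefactionCurve(estimator=estimator, points=points, step=step,
                                reps=reps, seed=seed)

    values = np.empty((reps, len(sizes)))
    for rep in range(reps):
        perm = rng.permutation(pool)
        acc = np.zeros(n_taxa, dtype=np.int64)
        prev = 0
        for col, n in enumerate(sizes):
            acc += np.bincount(perm[prev:n], minlength=n_taxa)
            prev = n
            values[rep, col] = fn(CountVector(acc), **kw)
    points = [
        (n, float(values[:, col].mean()), float(values[:, col].std(ddof=0)))
        for col, n in enumerate(sizes)
    ]
    return RarefactionCurve(estimator=estimator, points=points, step=step,
                            reps=reps, seed=seed)


def expected_sobs(v: CountVector | Sequence[int], n: int) -> float:
    """Closed-form expected observed richness of an n-individual subsample.

    E[S_obs(n)] = sum_t [1 - C(N - c_t, n) / C(N, n)] under sampling
    without replacement (hypergeometric per taxon).
    """
    v = _as_counts(v)
    n_total = v.n_individuals
    if not 0 <= n <= n_total:
        raise ValueError("n must be between 0 and the pool size")
    denom = math.comb(n_total, n)
    return float(sum(
        1.0 - math.comb(n_total - c, n) / denom
        for c in v.counts if c > 0
    ))


@dataclass(frozen=True)
class LogFit:
    """Least-squares fit of estimate = a*ln(n) + b."""

    a: float
    b: float
    rss: float

    def predict(self, n: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.log(n) + self.b


def fit_log(curve: RarefactionCurve) -> LogFit:
    """Fit mean ~ a*ln(n) + b by ordinary least squares."""
    n = curve.n_values
    if len(np.unique(n)) < 2:
        raise ValueError("need at least two distinct subsample sizes to fit")
    x = np.log(n.astype(float))
    y = curve.means
    (a, b), res = np.polyfit(x, y, 1, full=True)[:2]
    rss = float(res[0]) if len(res) else float(np.sum((y - (a * x + b)) ** 2))
    return LogFit(a=float(a), b=float(b), rss=rss)


def slope_at(fit: LogFit, n: int) -> float:
    """Derivative of the fitted logarithmic curve at sample size n: a/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return fit.a / n
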