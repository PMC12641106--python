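"""Observed-vs-null comparison of regional Delta+ values.

Dataset A holds one observed Delta+ per region; Dataset B pools the
per-region Delta+ of k richness-preserving null matrices.  Two two-sample
tests compare them:

* a Mann-Whitney U test on midranks, with tie-corrected normal
  approximation (no continuity correction), reporting U = min(U1, U2);
* a Monte-Carlo permutation test on the difference of medians (or means),
  shuffling group labels over the pooled values with group sizes fixed.

A group's distribution is called *patterned* (non-random) when both tests
reject at the chosen alpha, and *random* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .distinctness import DistinctnessResult
from .io import TaxdistError
from .nulls import NullEnsemble

__all__ = [
    "TestReport",
    "mann_whitney_u",
    "monte_carlo_permutation",
    "observed_vs_null_test",
    "per_replicate_tests",
]


@dataclass
class TestReport:
    """Result of the observed-vs-null comparison.

    ``U`` is min(U1, U2); ``z`` keeps its sign (positive when the first
    sample tends larger) and ``z_abs`` is its magnitude, the form usually
    printed.  ``p_permutation`` is present once the Monte-Carlo test ran.
    """

    U: float
    U1: float
    U2: float
    z: float
    p_asymptotic: float
    n1: int
    n2: int
    p_permutation: float | None = None
    B: int | None = None
    seed: int | None = None
    verdict: str | None = None

    @property
    def z_abs(self) -> float:
        return abs(self.z)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Two-sided Mann-Whitney U from midranks.

    Ties share midranks and enter the variance through the standard tie
    correction; with every pooled value identical the variance is zero and
    the report degenerates to z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise TaxdistError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestReport(U=float(min(u1, u2)), U1=float(u1), U2=float(u2),
                      z=float(z), p_asymptotic=p, n1=n1, n2=n2)


def monte_carlo_permutation(
    x: Sequence[float],
    y: Sequence[float],
    statistic: str = "median",
    B: int = 9_999,
    seed: int = 0,
) -> float:
    """Two-sided Monte-Carlo permutation p for a location difference.

    ``statistic`` is ``"median"`` (default) or ``"mean"``; the test shuffles
    group labels over the pooled sample B times with group sizes preserved
    and returns p = (1 + #{ |stat*| >= |stat| }) / (B + 1), so p is never
    smaller than 1/(B+1).  Symmetric in x and y.
    """
    if B < 99:
        raise TaxdistError("B must be >= 99 for a meaningful permutation p")
    if statistic not in ("median", "mean"):
        raise TaxdistError(f"unknown statistic {statistic!r}; use 'median' or 'mean'")
    stat = np.median if statistic == "median" else np.mean
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    observed = abs(stat(x) - stat(y))
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    perms = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
    null_stats = np.abs(stat(perms[:, :n1], axis=1) - stat(perms[:, n1:], axis=1))
    exceed = int((null_stats >= observed - 1e-12).sum())
    return (1 + exceed) / (B + 1)


def _defined_observed(results: Sequence[DistinctnessResult], regions: Sequence[str]) -> np.ndarray:
    by_region = {r.region: r for r in results}
    vals = []
    for region in regions:
        r = by_region.get(region)
        if r is not None and r.richness >= 2 and np.isfinite(r.delta_plus):
            vals.append(r.delta_plus)
    return np.asarray(vals, dtype=float)


def observed_vs_null_test(
    results: Sequence[DistinctnessResult],
    ensemble: NullEnsemble,
    B: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "median",
) -> TestReport:
    """Compare observed per-region Delta+ against the pooled null ensemble.

    x = one observed Delta+ per defined region; y = the k x regions null
    Delta+ values pooled.  Runs the U test and the permutation test; the
    verdict is ``"patterned"`` only when both reject at ``alpha``.
    """
    regions = list(ensemble.deltas.columns)
    x = _defined_observed(results, regions)
    if len(x) < 2:
        raise TaxdistError("need at least two regions with defined Delta+")
    y = ensemble.pooled_deltas()
    report = mann_whitney_u(x, y)
    report.p_permutation = monte_carlo_permutation(x, y, statistic=statistic, B=B, seed=seed)
    report.B = B
    report.seed = seed
    report.verdict = (
        "patterned"
        if (report.p_asymptotic < alpha and report.p_permutation < alpha)
        else "random"
    )
    return report


def per_replicate_tests(
    results: Sequence[DistinctnessResult],
    ensemble: NullEnsemble,
    B: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "median",
) -> list[TestReport]:
    """One observed-vs-null test per null matrix (k separate comparisons)."""
    regions = list(ensemble.deltas.columns)
    x = _defined_observed(results, regions)
    reports = []
    for i in range(ensemble.k):
        y = ensemble.deltas.iloc[i].to_numpy()
        rep = mann_whitney_u(x, y)
        rep.p_permutation = monte_carlo_permutation(x, y, statistic=statistic, B=B, seed=seed + i)
        rep.B = B
        rep.seed = seed + i
        rep.verdict = (
            "patterned"
            if (rep.p_asymptotic < alpha and rep.p_permutation < alpha)
            else "random"
        )
        reports.append(rep)
    return reports
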