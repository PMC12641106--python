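"""Randomization funnels and richness-constrained null models.

The *funnel* is the Monte-Carlo expectation and confidence band of Delta+
as a function of assemblage size s: repeatedly draw uniform size-s subsets
from the group's master species pool, compute Delta+ of each, and take the
replicate mean and the empirical central quantiles.  An observed regional
Delta+ below the lower limit indicates phylogenetic clustering (the region
holds closer relatives than chance predicts); above the upper limit,
overdispersion.

The *null models* randomize an occurrence matrix region by region while
preserving each region's richness exactly: every column's species are
redrawn uniformly without replacement from the master pool.  Row structure
(species range sizes) is deliberately unconstrained.

All randomness flows from a master integer seed through
``numpy.random.SeedSequence(master, key...)`` spawns, so every funnel,
region draw and replicate is bit-reproducible and independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distinctness import (
    DistinctnessResult,
    STEP1,
    WeightConvention,
    delta_plus,
    get_convention,
    weight_matrix,
)
from .io import OccurrenceMatrix, TaxonomyTable, TaxdistError

__all__ = [
    "FunnelConfig",
    "FunnelPoint",
    "NullEnsemble",
    "funnel",
    "funnel_table",
    "classify_regions",
    "randomize_assemblages",
    "generate_null_ensemble",
]


@dataclass(frozen=True)
class FunnelConfig:
    """Funnel construction parameters.

    replicates
        Random subsets drawn per richness value; 10,000 by default.
    ci_level
        Central coverage of the empirical band (0.95 -> 2.5%/97.5% limits).
    seed
        Master seed; the per-richness stream is spawned from (seed, s).
    """

    replicates: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class FunnelPoint:
    s: int
    mean: float
    ci_lower: float
    ci_upper: float


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _subset_deltas(W: np.ndarray, s: int, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Delta+ of ``replicates`` uniform size-s subsets, from a pooled weight matrix."""
    n = W.shape[0]
    # uniform random subsets via random-key argsort; chunked pair-sum gather
    out = np.empty(replicates, dtype=float)
    chunk = max(1, int(2**22 // max(s * s, 1)))
    for start in range(0, replicates, chunk):
        stop = min(start + chunk, replicates)
        idx = np.argsort(rng.random((stop - start, n)), axis=1)[:, :s]
        sub = W[idx[:, :, None], idx[:, None, :]]
        out[start:stop] = sub.sum(axis=(1, 2)) / (s * (s - 1))
    return out


def funnel(
    tax: TaxonomyTable,
    pool: Sequence[str],
    s: int,
    cfg: FunnelConfig = FunnelConfig(),
    conv: str | WeightConvention = STEP1,
) -> FunnelPoint:
    """Funnel expectation and CI limits at one richness value.

    Draws ``cfg.replicates`` uniform size-s subsets (without replacement)
    from ``pool``, computes Delta+ of each, and returns the replicate mean
    with the empirical central quantiles (linear / type-7 interpolation).
    At s == len(pool) only one subset exists, so the band has width zero.
    """
    pool = list(pool)
    if s < 2 or s > len(pool):
        raise TaxdistError(f"richness s={s} outside [2, |pool|={len(pool)}]")
    if s == len(pool):
        d = delta_plus(tax, pool, conv)
        return FunnelPoint(s, d, d, d)
    W = weight_matrix(tax, pool, conv)
    deltas = _subset_deltas(W, s, cfg.replicates, _rng(cfg.seed, s))
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha], method="linear")
    return FunnelPoint(s, float(deltas.mean()), float(lo), float(hi))


def funnel_table(
    tax: TaxonomyTable,
    pool: Sequence[str],
    s_values: Iterable[int],
    cfg: FunnelConfig = FunnelConfig(),
    conv: str | WeightConvention = STEP1,
) -> pd.DataFrame:
    """Funnel points for several richness values, sharing one weight matrix."""
    pool = list(pool)
    rows = []
    for s in sorted(set(int(s) for s in s_values)):
        pt = funnel(tax, pool, s, cfg, conv)
        rows.append(
            {
                "s": pt.s,
                "mean": pt.mean,
                "ci_lower": pt.ci_lower,
                "ci_upper": pt.ci_upper,
                "replicates": cfg.replicates,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)


def classify_regions(
    results: Sequence[DistinctnessResult],
    tax: TaxonomyTable,
    pool: Sequence[str],
    cfg: FunnelConfig = FunnelConfig(),
    conv: str | WeightConvention = STEP1,
) -> list[DistinctnessResult]:
    """Fill funnel fields and below/within/above flags for per-region results.

    The flag uses strict inequalities: an observed Delta+ exactly equal to a
    limit counts as ``within`` (ties go to the null).  Regions of richness
    < 2 keep ``undefined``.
    """
    table = funnel_table(
        tax, pool, [r.richness for r in results if r.richness >= 2], cfg, conv
    )
    points = {int(row.s): row for row in table.itertuples()}
    out: list[DistinctnessResult] = []
    for r in results:
        r = DistinctnessResult(**vars(r))
        if r.richness >= 2:
            pt = points[r.richness]
            r.funnel_mean, r.ci_lower, r.ci_upper = pt.mean, pt.ci_lower, pt.ci_upper
            if r.delta_plus > pt.ci_upper:
                r.flag = "above"
            elif r.delta_plus < pt.ci_lower:
                r.flag = "below"
            else:
                r.flag = "within"
        else:
            r.flag = "undefined"
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# richness-constrained null matrices


@dataclass
class NullEnsemble:
    """k richness-preserving randomized matrices with their per-region Delta+.

    ``deltas`` has one row per null matrix and one column per region that
    has richness >= 2 in the source matrix.
    """

    k: int
    matrices: list[OccurrenceMatrix]
    deltas: pd.DataFrame
    seed: int
    child_seeds: list[int] = field(default_factory=list)

    def pooled_deltas(self) -> np.ndarray:
        """All k x (defined regions) null Delta+ values as a flat array."""
        return self.deltas.to_numpy().ravel()


def randomize_assemblages(
    occ: OccurrenceMatrix,
    pool: Sequence[str],
    seed: int = 0,
) -> OccurrenceMatrix:
    """One richness-preserving randomization of an occurrence matrix.

    Each region independently receives a uniform sample (without
    replacement) of its original species count from ``pool``; column sums
    are therefore conserved exactly, while rows are unconstrained.
    """
    pool = list(dict.fromkeys(pool))
    richness = occ.richness()
    too_rich = richness[richness > len(pool)]
    if len(too_rich):
        raise TaxdistError(
            f"regions {list(too_rich.index)} are richer than the pool ({len(pool)} species)"
        )
    data = np.zeros((len(pool), len(occ.regions)), dtype=np.int8)
    for j, region in enumerate(occ.regions):
        s = int(richness[region])
        if s:
            picks = _rng(seed, j).choice(len(pool), size=s, replace=False)
            data[picks, j] = 1
    null = OccurrenceMatrix(pd.DataFrame(data, index=pool, columns=occ.regions))
    assert (null.richness() == richness).all(), "null draw broke richness conservation"
    return null


def generate_null_ensemble(
    occ: OccurrenceMatrix,
    pool: Sequence[str],
    tax: TaxonomyTable,
    k: int = 3,
    seed: int = 0,
    conv: str | WeightConvention = STEP1,
) -> NullEnsemble:
    """k independent richness-preserving nulls plus their per-region Delta+.

    Child seeds are spawned deterministically from the master seed, so the
    same master seed always reproduces the same ensemble.  Regions with
    richness < 2 are omitted from the Delta+ table.
    """
    if k < 1:
        raise TaxdistError("k must be >= 1")
    conv = get_convention(conv)
    richness = occ.richness()
    defined = [r for r in occ.regions if richness[r] >= 2]
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(k)]
    matrices, rows = [], []
    for child in child_seeds:
        null = randomize_assemblages(occ, pool, seed=child)
        matrices.append(null)
        rows.append({r: delta_plus(tax, null.assemblage(r), conv) for r in defined})
    deltas = pd.DataFrame(rows, columns=defined)
    return NullEnsemble(k=k, matrices=matrices, deltas=deltas, seed=seed, child_seeds=child_seeds)
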