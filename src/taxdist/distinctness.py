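"""Average taxonomic distinctness (Delta+) from a ranked taxonomy.

Delta+ of a presence/absence assemblage is the mean *distinctness weight*
over all s(s-1)/2 unordered species pairs,

    Delta+ = sum_{i<j} w_ij / [s (s - 1) / 2],

where w_ij is a step value determined by the lowest Linnaean rank the two
species share: congeners are nearest, then confamilials, then members of
the same order, the same class, and finally species in different classes.
Delta+ is independent of richness in expectation, which is what makes the
funnel-based null comparison meaningful.

Two step dialects are provided.  ``step1`` (default) starts at 1 for
congeners and rises to 5 across classes.  ``w0`` starts at 0 and rises to
4.  Since every weight differs by exactly 1 between the dialects, the two
Delta+ values differ by exactly 1 for any assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import OccurrenceMatrix, TaxonomyTable, TaxdistError

__all__ = [
    "WeightConvention",
    "STEP1",
    "W0",
    "get_convention",
    "DistinctnessResult",
    "pair_weight",
    "weight_matrix",
    "delta_plus",
    "delta_plus_from_weights",
    "select_species",
    "group_delta_table",
    "richness_table",
]


@dataclass(frozen=True)
class WeightConvention:
    """Step values by the lowest shared rank of a species pair.

    Weights must strictly increase with taxonomic remoteness.
    """

    name: str
    congeneric: float
    confamilial: float
    same_order: float
    same_class: float
    cross_class: float

    def __post_init__(self) -> None:
        steps = self.steps
        if not np.all(np.diff(steps) > 0):
            raise ValueError(f"weights must strictly increase with remoteness, got {steps}")

    @property
    def steps(self) -> np.ndarray:
        """Array indexed by remoteness level 0..4 (congeneric .. cross-class)."""
        return np.array(
            [self.congeneric, self.confamilial, self.same_order, self.same_class, self.cross_class],
            dtype=float,
        )


STEP1 = WeightConvention("step1", 1, 2, 3, 4, 5)
W0 = WeightConvention("w0", 0, 1, 2, 3, 4)

_CONVENTIONS = {"step1": STEP1, "w0": W0}


def get_convention(name: str | WeightConvention) -> WeightConvention:
    if isinstance(name, WeightConvention):
        return name
    try:
        return _CONVENTIONS[name]
    except KeyError:
        raise TaxdistError(f"unknown weight dialect {name!r}; choose from {sorted(_CONVENTIONS)}") from None


@dataclass
class DistinctnessResult:
    """Per-region Delta+ with (optional) funnel expectation and 95% limits.

    ``flag`` is ``undefined`` when richness < 2 (no pairs exist), otherwise
    one of ``below`` / ``within`` / ``above`` relative to the funnel CI once
    :func:`taxdist.nulls.classify_regions` has filled the funnel fields.
    """

    region: str
    richness: int
    delta_plus: float  # nan when undefined
    funnel_mean: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    flag: str = "unclassified"


def _remoteness_levels(tax: TaxonomyTable, species: Sequence[str]) -> np.ndarray:
    """Pairwise remoteness level matrix: 0 congeneric ... 4 cross-class.

    Diagonal entries are 0 by construction and are never read by Delta+.
    """
    codes = tax.lineage_codes(species)  # (n, 4): genus, family, order, class
    shared = np.zeros((len(species), len(species)), dtype=np.int8)
    for k in range(4):
        shared += codes[:, k][:, None] == codes[None, :, k]
    return 4 - shared


def pair_weight(
    tax: TaxonomyTable,
    sp_i: str,
    sp_j: str,
    conv: str | WeightConvention = STEP1,
) -> float:
    """Distinctness weight of one species pair (symmetric in its arguments)."""
    conv = get_convention(conv)
    if sp_i == sp_j:
        raise TaxdistError("self-pairs have no distinctness weight (Delta+ sums over i < j)")
    levels = _remoteness_levels(tax, [sp_i, sp_j])
    return float(conv.steps[levels[0, 1]])


def weight_matrix(
    tax: TaxonomyTable,
    species: Sequence[str],
    conv: str | WeightConvention = STEP1,
) -> np.ndarray:
    """Symmetric pairwise weight matrix with a zero diagonal.

    The diagonal is set to 0 purely as a sentinel: self-pairs never enter
    Delta+, whose sum runs over i < j only.
    """
    if len(set(species)) != len(species):
        raise TaxdistError("species list passed to weight_matrix contains duplicates")
    conv = get_convention(conv)
    W = conv.steps[_remoteness_levels(tax, species)]
    np.fill_diagonal(W, 0.0)
    return W


def delta_plus_from_weights(W: np.ndarray) -> float:
    """Delta+ from a precomputed symmetric weight matrix (zero diagonal)."""
    s = W.shape[0]
    if s < 2:
        raise TaxdistError(f"Delta+ undefined for richness {s} < 2")
    return float(W.sum() / (s * (s - 1)))


def delta_plus(
    tax: TaxonomyTable,
    assemblage: Iterable[str],
    conv: str | WeightConvention = STEP1,
) -> float:
    """Average taxonomic distinctness of an assemblage (order-invariant)."""
    species = sorted(set(assemblage))
    if len(species) < 2:
        raise TaxdistError(f"Delta+ undefined for richness {len(species)} < 2")
    return delta_plus_from_weights(weight_matrix(tax, species, conv))


# ---------------------------------------------------------------------------
# group selection and per-region tables

GroupFilter = Callable[[pd.Series], bool]


def select_species(
    tax: TaxonomyTable,
    rank: str | None = None,
    value: str | Iterable[str] | None = None,
    species: Iterable[str] | None = None,
    include_extinct: bool = True,
) -> list[str]:
    """Resolve a taxon predicate to a species list.

    A group can be a whole rank value (``rank="class", value="Mammalia"``),
    a set of rank values (e.g. the pinniped families), or an explicit
    species list.  Extinct-flagged species are included by default.
    """
    df = tax.frame
    if species is not None:
        wanted = {" ".join(s.split()) for s in species}
        unknown = wanted - set(df["species"])
        if unknown:
            raise TaxdistError(f"species not in taxonomy: {sorted(unknown)}")
        mask = df["species"].isin(wanted)
    elif rank is not None and value is not None:
        if rank not in df.columns:
            raise TaxdistError(f"unknown rank {rank!r}")
        values = {value} if isinstance(value, str) else set(value)
        mask = df[rank].isin(values)
    else:
        mask = pd.Series(True, index=df.index)
    if not include_extinct and "extinct" in df.columns:
        mask &= ~df["extinct"]
    return df.loc[mask, "species"].tolist()


def group_delta_table(
    tax: TaxonomyTable,
    occ: OccurrenceMatrix,
    group: Iterable[str] | None = None,
    conv: str | WeightConvention = STEP1,
) -> list[DistinctnessResult]:
    """Delta+ of each regional assemblage, restricted to a species group.

    Regions where the group has fewer than two species get ``flag=undefined``
    and a NaN Delta+.  Funnel fields stay unset until classification.
    """
    group_set = set(group) if group is not None else set(occ.species)
    if len(group_set & set(occ.species)) < 2 or len(group_set) < 2:
        raise TaxdistError("group must contain at least two species present in the matrix")
    results: list[DistinctnessResult] = []
    for region in occ.regions:
        members = [sp for sp in occ.assemblage(region) if sp in group_set]
        s = len(members)
        if s < 2:
            results.append(DistinctnessResult(region, s, float("nan"), flag="undefined"))
        else:
            results.append(DistinctnessResult(region, s, delta_plus(tax, members, conv)))
    return results


def richness_table(
    occ: OccurrenceMatrix,
    group: Iterable[str] | None = None,
) -> pd.Series:
    """Per-region species counts for a group, sorted descending.

    Ties keep the matrix's canonical region order (pandas stable sort).
    """
    if group is None:
        counts = occ.richness()
    else:
        group_set = set(group)
        rows = [sp for sp in occ.species if sp in group_set]
        counts = occ.frame.loc[rows].sum(axis=0).astype(int)
    return counts.sort_values(ascending=False, kind="stable")
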