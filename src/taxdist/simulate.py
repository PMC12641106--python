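"""Synthetic taxonomies and occurrence matrices with controlled structure.

The generator emulates the shape of a regional marine-tetrapod dataset: a
five-rank Linnaean taxonomy with highly uneven clade sizes (geometric
species-per-genus counts, so one family can hold the bulk of a group, the
way a single radiating family dominates real sea-snake lists), and
regional assemblages that are uniform draws, phylogenetically *clustered*
(mostly congeners/confamilials of one seed clade), or *overdispersed*
(spread across as many orders as possible).  A clustering intensity
``kappa`` in [0, 1] interpolates each structured mode toward uniform;
``kappa = 0`` is exactly the random mode.

Everything is deterministic given a seed, so whole-pipeline tests need no
external data.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OccurrenceMatrix, TaxonomyTable

__all__ = [
    "SyntheticSpec",
    "generate_taxonomy",
    "generate_assemblages",
    "paper_like_fixture",
    "FIXTURE_SHA256",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters of a synthetic study.

    Defaults mimic the real study's scale: a pool of roughly a hundred
    species dominated by one radiating clade, fifteen regions, and regional
    richness anywhere from 2 to 60 species (clipped to the pool size).
    ``modes`` assigns an assembly mode per region label; unlisted regions
    are ``random``.
    """

    n_classes: int = 1
    orders_per_class: int = 4
    families_per_order: int = 2
    genera_per_family: int = 3
    species_geometric_p: float = 0.25
    n_regions: int = 15
    richness_range: tuple[int, int] = (2, 60)
    modes: Mapping[str, str] = field(default_factory=dict)
    kappa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_classes", "orders_per_class", "families_per_order", "genera_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.species_geometric_p <= 1.0:
            raise ValueError("species_geometric_p must lie in (0, 1]")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        lo, hi = self.richness_range
        if lo < 2 or hi < lo:
            raise ValueError("richness_range must satisfy 2 <= lo <= hi")
        for mode in self.modes.values():
            if mode not in ("random", "clustered", "overdispersed"):
                raise ValueError(f"unknown assembly mode {mode!r}")

    def region_labels(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def generate_taxonomy(spec: SyntheticSpec, seed: int = 0) -> TaxonomyTable:
    """Draw a rank-consistent taxonomy with geometric clade sizes.

    Species-per-genus counts are geometric (truncated at >= 1) with
    parameter ``spec.species_geometric_p``; a small p makes a few genera --
    and hence their family -- hold most species.
    """
    rng = _rng(seed, 0)
    records = []
    g = 0
    for c in range(spec.n_classes):
        for o in range(spec.orders_per_class):
            for f in range(spec.families_per_order):
                for _ in range(spec.genera_per_family):
                    g += 1
                    n_sp = int(rng.geometric(spec.species_geometric_p))
                    for s in range(n_sp):
                        records.append(
                            (
                                f"Genus_{g} species_{s + 1}",
                                f"Genus_{g}",
                                f"Family_{c + 1}_{o + 1}_{f + 1}",
                                f"Order_{c + 1}_{o + 1}",
                                f"Class_{c + 1}",
                            )
                        )
    return TaxonomyTable.from_records(records)


def _draw_region(
    tax: TaxonomyTable,
    s: int,
    mode: str,
    kappa: float,
    rng: np.random.Generator,
) -> list[str]:
    df = tax.frame
    species = df["species"].to_numpy()
    if mode == "random" or kappa == 0.0:
        return list(rng.choice(species, size=s, replace=False))

    chosen: list[str] = []
    remaining = set(species)
    if mode == "clustered":
        # seed clade via a uniformly drawn seed species, so big radiations
        # seed clusters in proportion to their size; only families able to
        # host the whole assemblage are eligible (a smaller seed clade would
        # force the uniform fallback and destroy the requested structure)
        fam_sizes = df["family"].value_counts()
        feasible = fam_sizes[fam_sizes >= s]
        if len(feasible):
            candidates = df.loc[df["family"].isin(feasible.index), "species"].to_numpy()
        else:
            candidates = df.loc[df["family"] == fam_sizes.index[0], "species"].to_numpy()
        seed_species = rng.choice(candidates)
        family = df.loc[df["species"] == seed_species, "family"].iloc[0]
        clade = set(df.loc[df["family"] == family, "species"])
        for _ in range(s):
            pool = clade & remaining if rng.random() < kappa else remaining
            if not pool:
                pool = remaining
                logger.info(
                    "clustered draw exhausted family %s; falling back to uniform", family
                )
            pick = rng.choice(sorted(pool))
            chosen.append(pick)
            remaining.discard(pick)
        return chosen

    if mode == "overdispersed":
        # round-robin across orders: maximise the number of distinct orders
        # represented before any order contributes a second species
        by_order = {
            o: list(rng.permutation(sub["species"].to_numpy()))
            for o, sub in df.groupby("order")
        }
        order_cycle = list(rng.permutation(sorted(by_order)))
        i = 0
        for _ in range(s):
            if rng.random() < kappa:
                for _ in range(len(order_cycle)):
                    o = order_cycle[i % len(order_cycle)]
                    i += 1
                    if by_order[o]:
                        pick = by_order[o].pop()
                        break
                else:  # pragma: no cover - all orders exhausted
                    pick = rng.choice(sorted(remaining))
            else:
                pick = rng.choice(sorted(remaining))
                for members in by_order.values():
                    if pick in members:
                        members.remove(pick)
            chosen.append(pick)
            remaining.discard(pick)
        return chosen

    raise ValueError(f"unknown assembly mode {mode!r}")


def generate_assemblages(
    tax: TaxonomyTable,
    spec: SyntheticSpec,
    seed: int = 0,
) -> OccurrenceMatrix:
    """Draw one occurrence matrix over ``spec.n_regions`` regions.

    Per region: richness is uniform over ``spec.richness_range`` (clipped to
    the pool size), then species are sampled according to the region's
    assembly mode at intensity ``spec.kappa``.  Infeasible clustered draws
    fall back to uniform sampling for the remainder and are logged.
    """
    n = len(tax)
    lo = min(spec.richness_range[0], n)
    hi = min(spec.richness_range[1], n)
    labels = spec.region_labels()
    data = pd.DataFrame(0, index=tax.species, columns=labels, dtype=np.int8)
    for j, label in enumerate(labels):
        rng = _rng(seed, j + 1)
        s = int(rng.integers(lo, hi + 1))
        mode = spec.modes.get(label, "random")
        for sp in _draw_region(tax, s, mode, spec.kappa, rng):
            data.loc[sp, label] = 1
    return OccurrenceMatrix(data)


# ---------------------------------------------------------------------------
# frozen paper-like fixture

_FIXTURE_TAXONOMY_CSV = """\
species,genus,family,order,class
Radiaster unus,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster duo,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster tres,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster quattuor,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster quinque,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster sex,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster septem,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster octo,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster novem,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster decem,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster undecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster duodecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster tredecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster quattuordecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster quindecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Radiaster sedecim,Radiaster,Radiatidae,Serpentiformes,Pelagia
Costella prima,Costella,Radiatidae,Serpentiformes,Pelagia
Costella secunda,Costella,Radiatidae,Serpentiformes,Pelagia
Costella tertia,Costella,Radiatidae,Serpentiformes,Pelagia
Costella quarta,Costella,Radiatidae,Serpentiformes,Pelagia
Lentus maior,Lentus,Lentidae,Serpentiformes,Pelagia
Lentus minor,Lentus,Lentidae,Serpentiformes,Pelagia
Carapax magnus,Carapax,Carapacidae,Testudiformes,Pelagia
Carapax parvus,Carapax,Carapacidae,Testudiformes,Pelagia
Tardus solus,Tardus,Tardidae,Testudiformes,Pelagia
Durus ferox,Durus,Duridae,Crocodiliformes,Pelagia
Durus mitis,Durus,Duridae,Crocodiliformes,Pelagia
Aptus borealis,Aptus,Aptidae,Pinguiformes,Pelagia
Aptus australis,Aptus,Aptidae,Pinguiformes,Pelagia
Gelidus profundus,Gelidus,Gelidae,Pinguiformes,Pelagia
"""

_FIXTURE_OCCURRENCE_CSV = """\
species,ClusterBay,SpreadSea,MidSea,BroadSea,NarrowStrait,EmptyRock
Radiaster unus,1,0,1,1,0,0
Radiaster duo,1,0,1,1,0,0
Radiaster tres,1,0,1,0,0,0
Radiaster quattuor,1,0,0,1,0,0
Radiaster quinque,1,0,0,0,0,0
Radiaster sex,1,0,0,0,0,0
Radiaster septem,1,0,0,0,0,0
Radiaster octo,1,0,0,0,0,0
Radiaster novem,1,0,0,0,0,0
Radiaster decem,1,0,0,0,0,1
Radiaster undecim,0,0,0,1,0,0
Radiaster duodecim,0,0,0,0,0,0
Radiaster tredecim,0,0,0,0,0,0
Radiaster quattuordecim,0,0,0,0,0,0
Radiaster quindecim,0,0,0,0,0,0
Radiaster sedecim,0,0,0,0,0,0
Costella prima,0,0,1,1,0,0
Costella secunda,0,0,0,1,0,0
Costella tertia,0,0,0,0,0,0
Costella quarta,0,0,0,0,0,0
Lentus maior,0,1,0,1,1,0
Lentus minor,0,0,0,0,1,0
Carapax magnus,0,1,1,1,0,0
Carapax parvus,0,0,0,1,0,0
Tardus solus,0,0,1,0,0,0
Durus ferox,0,1,0,1,0,0
Durus mitis,0,0,0,0,0,0
Aptus borealis,0,1,1,1,0,0
Aptus australis,0,0,0,0,0,0
Gelidus profundus,0,0,1,0,0,0
"""

#: sha256 over the two frozen fixture CSV payloads, in order.
FIXTURE_SHA256 = "850e1be95a5f50212c1183220ecb658a63fb3f918bc10327123cdbcfec68ad40"


def paper_like_fixture() -> tuple[TaxonomyTable, OccurrenceMatrix]:
    """The frozen demonstration dataset: 30 species, 6 regions.

    One radiating snake-like family (Radiatidae, 20 of 30 species, 14 in a
    single genus) plus turtle-, crocodile- and pinniped-like clades spread
    over three further orders.  Region compositions are fixed so that all
    three funnel outcomes occur: ``ClusterBay`` (10 congeners) sits below
    the funnel, ``SpreadSea`` (one species from each of the four orders)
    sits above it, and the mixed regions fall within; ``EmptyRock`` has
    richness 1 and exercises the undefined flag.
    """
    digest = hashlib.sha256(
        (_FIXTURE_TAXONOMY_CSV + _FIXTURE_OCCURRENCE_CSV).encode()
    ).hexdigest()
    if digest != FIXTURE_SHA256:
        raise RuntimeError("paper-like fixture payload corrupted (checksum mismatch)")
    tax = TaxonomyTable(pd.read_csv(_io.StringIO(_FIXTURE_TAXONOMY_CSV)))
    occ = OccurrenceMatrix(pd.read_csv(_io.StringIO(_FIXTURE_OCCURRENCE_CSV), index_col=0))
    return tax, occ
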