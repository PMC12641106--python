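"""Reading, validating and writing taxonomy and occurrence tables.

The two core inputs of a taxonomic-distinctness study are

* a ranked **taxonomy table** — one row per species with its Linnaean
  lineage (species, genus, family, order, class), from which pairwise
  distinctness weights are derived, and
* a **presence/absence occurrence matrix** — species in rows, regions in
  columns, cells in {0, 1}; each column defines one regional assemblage.

The canonical interchange format is delimited text (CSV/TSV).  A workbook
with the same content can be converted once with :func:`convert_xlsx`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CANONICAL_REGIONS",
    "REGION_NAMES",
    "TaxdistError",
    "SchemaError",
    "DataValidationError",
    "TaxonomyTable",
    "OccurrenceMatrix",
    "ValidationReport",
    "read_taxonomy",
    "read_occurrence",
    "write_taxonomy",
    "write_occurrence",
    "validate_dataset",
    "latitude_band",
    "convert_xlsx",
]

#: Rank columns, most to least specific. "class" is a Python keyword, so the
#: in-memory frames use exactly these lowercase header strings.
RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class")

#: Canonical 15-region vocabulary: short label -> full name.
REGION_NAMES: dict[str, str] = {
    "NAO": "North Atlantic Ocean",
    "TAO": "Tropical Atlantic Ocean",
    "SAO": "South Atlantic Ocean",
    "NPO": "North Pacific Ocean",
    "TPO": "Tropical Pacific Ocean",
    "SPO": "South Pacific Ocean",
    "TIO": "Tropical Indian Ocean",
    "SIO": "South Indian Ocean",
    "AO": "Arctic Ocean",
    "SO": "Southern Ocean",
    "MED": "Mediterranean Sea",
    "RED": "Red Sea",
    "PEG": "Persian Gulf",
    "GOM": "Gulf of Mexico",
    "CAR": "Caribbean Sea",
}

CANONICAL_REGIONS: tuple[str, ...] = tuple(REGION_NAMES)

#: Accepted aliases (full names, case-insensitive) -> canonical label.
_REGION_ALIASES: dict[str, str] = {name.lower(): lab for lab, name in REGION_NAMES.items()}
_REGION_ALIASES.update({lab.lower(): lab for lab in REGION_NAMES})


class TaxdistError(Exception):
    """Base class for all package errors."""


class SchemaError(TaxdistError):
    """A required column or sheet is missing or malformed."""


class DataValidationError(TaxdistError):
    """Content violates a dataset invariant (duplicates, bad cells, ...)."""


def _clean_name(s: object) -> str:
    """Trim and collapse internal whitespace; exact-string matching after this."""
    return " ".join(str(s).split())


@dataclass(frozen=True)
class TaxonomyTable:
    """A validated five-rank taxonomy, one row per species.

    Invariants (enforced at construction): species names unique after
    whitespace normalisation; all five ranks non-empty; each genus belongs
    to exactly one family, each family to one order, each order to one
    class.  An optional boolean ``extinct`` flag per species is carried
    through but never affects weights.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in RANKS if c not in df.columns]
        if missing:
            raise SchemaError(f"taxonomy is missing rank column(s): {', '.join(missing)}")
        df = df.copy()
        for c in RANKS:
            df[c] = df[c].map(_clean_name)
            empty = df[c] == ""
            if empty.any():
                rows = (df.index[empty] + 1).tolist()
                raise DataValidationError(f"empty '{c}' value in row(s) {rows}")
        dup = df["species"][df["species"].duplicated()].unique().tolist()
        if dup:
            raise DataValidationError(f"duplicate species: {', '.join(sorted(dup))}")
        for child, parent in (("genus", "family"), ("family", "order"), ("order", "class")):
            nunique = df.groupby(child)[parent].nunique()
            bad = nunique[nunique > 1]
            if len(bad):
                conflicts = []
                for name in bad.index:
                    parents = sorted(df.loc[df[child] == name, parent].unique())
                    conflicts.append(f"{child} '{name}' maps to {parent}s {parents}")
                raise DataValidationError("rank inconsistency: " + "; ".join(conflicts))
        if "extinct" in df.columns:
            df["extinct"] = (
                df["extinct"]
                .map(lambda v: str(v).strip().lower() in {"1", "true", "yes", "t"})
                .astype(bool)
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[Sequence[str]], extinct: Sequence[bool] | None = None
    ) -> "TaxonomyTable":
        """Build from (species, genus, family, order, class) tuples."""
        df = pd.DataFrame(list(records), columns=list(RANKS))
        if extinct is not None:
            df["extinct"] = list(extinct)
        return cls(df)

    # -- accessors --------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return self.frame["species"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, species: str) -> bool:
        return _clean_name(species) in set(self.frame["species"])

    def lineage(self, species: str) -> tuple[str, str, str, str]:
        """(genus, family, order, class) of one species."""
        sp = _clean_name(species)
        row = self.frame[self.frame["species"] == sp]
        if row.empty:
            raise KeyError(f"unknown species: {species!r}")
        r = row.iloc[0]
        return (r["genus"], r["family"], r["order"], r["class"])

    def lineage_codes(self, species: Sequence[str]) -> np.ndarray:
        """Integer-coded lineages, shape (len(species), 4).

        Column j holds factor codes of rank ``RANKS[j + 1]``; two species
        share a rank iff their codes in that column are equal.  Used to
        vectorise pairwise weight computation.
        """
        df = self.frame.set_index("species")
        try:
            sub = df.loc[[_clean_name(s) for s in species]]
        except KeyError as exc:
            raise KeyError(f"species not in taxonomy: {exc.args[0]}") from None
        cols = []
        for rank in RANKS[1:]:
            codes, _ = pd.factorize(self.frame[rank])
            mapping = dict(zip(self.frame[rank], codes))
            cols.append(sub[rank].map(mapping).to_numpy())
        return np.stack(cols, axis=1)

    def subset(self, species: Iterable[str]) -> "TaxonomyTable":
        keep = {_clean_name(s) for s in species}
        return TaxonomyTable(self.frame[self.frame["species"].isin(keep)].reset_index(drop=True))


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Species x region presence/absence matrix (cells strictly 0/1)."""

    frame: pd.DataFrame = field(repr=False)  # index: species, columns: region labels

    def __post_init__(self) -> None:
        df = self.frame
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise DataValidationError("occurrence matrix is empty")
        df = df.copy()
        df.index = [_clean_name(s) for s in df.index]
        df.index.name = "species"
        df.columns = [_clean_name(c) for c in df.columns]
        dup = pd.Index(df.index)[pd.Index(df.index).duplicated()].unique().tolist()
        if dup:
            raise DataValidationError(f"duplicate species rows: {', '.join(sorted(dup))}")
        for j, col in enumerate(df.columns):
            vals = df[col]
            ok = vals.isin([0, 1, "0", "1", 0.0, 1.0, False, True])
            if not ok.all():
                i = int(np.flatnonzero(~ok.to_numpy())[0])
                raise DataValidationError(
                    f"non-0/1 cell {vals.iloc[i]!r} at species {df.index[i]!r}, "
                    f"region {col!r} (row {i + 1}, column {j + 2})"
                )
        object.__setattr__(self, "frame", df.astype(np.int8))

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    @property
    def regions(self) -> list[str]:
        return list(self.frame.columns)

    def richness(self) -> pd.Series:
        """Per-region species counts (column sums)."""
        return self.frame.sum(axis=0).astype(int)

    def assemblage(self, region: str) -> list[str]:
        """Species present in one region."""
        col = self.frame[region]
        return list(col.index[col == 1])

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass
class ValidationReport:
    """Cross-check of an occurrence matrix against its taxonomy.

    ``fatal`` entries block downstream analysis; ``warnings`` do not.
    """

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        lines = [f"FATAL: {m}" for m in self.fatal] + [f"WARNING: {m}" for m in self.warnings]
        return "\n".join(lines) if lines else "dataset valid"


def validate_dataset(tax: TaxonomyTable, occ: OccurrenceMatrix) -> ValidationReport:
    """Report species unknown to the taxonomy (fatal), species never present
    (warning) and regions of richness < 2 where Delta+ is undefined (warning).

    Pure function: neither input is modified, and repeated calls return
    identical reports.
    """
    report = ValidationReport()
    tax_species = set(tax.species)
    for sp in occ.species:
        if sp not in tax_species:
            report.fatal.append(f"species {sp!r} present in occurrence matrix but absent from taxonomy")
    present_somewhere = {sp for sp in occ.species if occ.frame.loc[sp].sum() > 0}
    for sp in tax.species:
        if sp not in present_somewhere:
            report.warnings.append(f"species {sp!r} in taxonomy is never present in any region")
    for region, s in occ.richness().items():
        if s < 2:
            report.warnings.append(
                f"region {region!r} has richness {s} < 2; Delta+ undefined there"
            )
    return report


# ---------------------------------------------------------------------------
# latitude bands


def latitude_band(latitude: float) -> str:
    """Map a latitude to its study band.

    Bands: Arctic (>= 60), North (23..60), Tropical (-23..23), South
    (-60..-23), Southern (<= -60).  A boundary latitude belongs to the
    poleward band, so 60 -> Arctic, 23 -> North, -23 -> South,
    -60 -> Southern; the bands partition [-90, 90].
    """
    lat = float(latitude)
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if lat >= 60:
        return "Arctic"
    if lat >= 23:
        return "North"
    if lat > -23:
        return "Tropical"
    if lat > -60:
        return "South"
    return "Southern"


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_taxonomy(path: str | Path, dialect: Mapping[str, str] | None = None) -> TaxonomyTable:
    """Read a taxonomy CSV/TSV.

    Parameters
    ----------
    path
        Delimited text file with a header row.  The delimiter is sniffed
        (comma or tab).
    dialect
        Optional mapping from the five rank names to the file's actual
        column headers, e.g. ``{"class": "Class name"}``.  Unmapped ranks
        must appear under their own names (any capitalisation).
    """
    df = _read_delimited(path)
    df.columns = [str(c).strip() for c in df.columns]
    rename: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for rank in RANKS:
        src = (dialect or {}).get(rank, rank)
        if src in df.columns:
            rename[src] = rank
        elif src.lower() in lower:
            rename[lower[src.lower()]] = rank
        else:
            raise SchemaError(f"taxonomy file {path} has no column for rank '{rank}'")
    if "extinct" in lower and "extinct" not in rename.values():
        rename[lower["extinct"]] = "extinct"
    df = df.rename(columns=rename)
    keep = [c for c in (*RANKS, "extinct") if c in df.columns]
    return TaxonomyTable(df[keep])


def read_occurrence(path: str | Path) -> OccurrenceMatrix:
    """Read an occurrence CSV/TSV: first column species, then one 0/1 column
    per region."""
    df = _read_delimited(path, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"occurrence file {path} needs a species column plus region columns")
    df = df.set_index(df.columns[0])
    return OccurrenceMatrix(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.frame.to_csv(path, index=False)


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.frame.to_csv(path)


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    first = text.splitlines()[0] if text else ""
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(_io.StringIO(text), sep=sep, skipinitialspace=True, **kwargs)


# ---------------------------------------------------------------------------
# one-shot workbook conversion


def convert_xlsx(
    path: str | Path,
    sheet: str | int = 0,
    dialect: Mapping[str, str] | None = None,
    region_columns: Sequence[str] | None = None,
) -> tuple[TaxonomyTable, OccurrenceMatrix]:
    """Convert a combined workbook sheet into the two canonical tables.

    The sheet is expected to carry the five rank columns plus one 0/1 column
    per region on the same rows (the usual layout of a combined species x
    region workbook).  Region columns are auto-detected as the columns whose
    header matches the canonical vocabulary (label or full name,
    case-insensitive) unless ``region_columns`` names them explicitly.
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    raw.columns = [str(c).strip() for c in raw.columns]
    lower = {c.lower(): c for c in raw.columns}

    rename: dict[str, str] = {}
    for rank in RANKS:
        src = (dialect or {}).get(rank, rank)
        if src in raw.columns:
            rename[src] = rank
        elif src.lower() in lower:
            rename[lower[src.lower()]] = rank
        else:
            raise SchemaError(f"sheet has no column for rank '{rank}'")
    tax = TaxonomyTable(raw.rename(columns=rename)[list(RANKS)])

    if region_columns is None:
        region_columns = [c for c in raw.columns if c.lower() in _REGION_ALIASES]
        if not region_columns:
            raise SchemaError(
                "no region columns recognised; pass region_columns= explicitly"
            )
    occ_df = raw[list(region_columns)].copy()
    occ_df.columns = [_REGION_ALIASES.get(str(c).lower(), str(c)) for c in region_columns]
    occ_df.index = tax.frame["species"]
    occ = OccurrenceMatrix(occ_df)
    return tax, occ
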