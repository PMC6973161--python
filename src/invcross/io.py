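"""Readers, writers and the shared data model for BC1 genotype data.

A BC1 individual reveals exactly one parental gamete of the F1, so each SNP
call is two-valued: homozygous for the recurrent parent (``REC``) or
heterozygous (``HET``), plus ``MISSING`` for failed calls.  Calls are stored
as an ``int8`` matrix (individuals x markers) with the encoding
``REC=0, HET=1, MISSING=-1``; marker order always follows the marker map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REC: int = 0
HET: int = 1
MISSING: int = -1

_CHROMOSOMES = ("1", "2", "3", "4", "5")


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


def _normalise_chromosome(label: object) -> str:
    text = str(label).strip()
    lowered = text.lower()
    if lowered.startswith("chr"):
        text = text[3:]
    if text not in _CHROMOSOMES:
        raise ValidationError(f"unknown chromosome label {label!r}")
    return text


@dataclass(frozen=True)
class Dialect:
    """Symbol set used in genotype score files.

    The default matches supplementary-spreadsheet conventions: ``A`` for the
    recurrent homozygote, ``H`` for the heterozygote, ``-`` or an empty cell
    for a failed call.
    """

    rec: str = "A"
    het: str = "H"
    missing: tuple[str, ...] = ("-", "")

    def encode(self, symbol: object, *, where: str = "") -> int:
        text = "" if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)) else str(symbol).strip()
        if text == self.rec:
            return REC
        if text == self.het:
            return HET
        if text in self.missing:
            return MISSING
        raise ValidationError(f"call symbol {text!r} outside dialect {where}".strip())

    def decode(self, code: int) -> str:
        if code == REC:
            return self.rec
        if code == HET:
            return self.het
        return self.missing[0]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP markers with chromosome assignment and physical position.

    ``table`` has columns ``marker_id``, ``chromosome``, ``pos_bp`` and
    ``order_index`` (1-based within chromosome), sorted by
    ``(chromosome, pos_bp)``.  Physical positions are 1-based base pairs;
    the interval between adjacent markers is half-open ``[pos_i, pos_{i+1})``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            raise ValidationError("no markers")
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValidationError(f"duplicate marker id(s): {dups}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            if len(sub) < 2:
                raise ValidationError(f"chromosome {chrom} has fewer than 2 markers")
            pos = sub["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(f"positions not strictly increasing on chromosome {chrom}")

    @classmethod
    def from_records(cls, records: list[tuple[str, object, int]]) -> "MarkerMap":
        """Build a map from ``(marker_id, chromosome, pos_bp)`` records."""
        df = pd.DataFrame(records, columns=["marker_id", "chromosome", "pos_bp"])
        df["chromosome"] = df["chromosome"].map(_normalise_chromosome)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df = df.sort_values(["chromosome", "pos_bp"], kind="mergesort").reset_index(drop=True)
        df["order_index"] = df.groupby("chromosome", sort=False).cumcount() + 1
        return cls(df)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def __len__(self) -> int:
        return len(self.table)

    def chromosome_slice(self, chromosome: str) -> slice:
        """Column slice (into map order) covering one chromosome."""
        chrom = _normalise_chromosome(chromosome)
        idx = np.flatnonzero((self.table["chromosome"] == chrom).to_numpy())
        if idx.size == 0:
            raise ValidationError(f"chromosome {chromosome!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions_mbp(self, chromosome: str) -> np.ndarray:
        sl = self.chromosome_slice(chromosome)
        return self.table["pos_bp"].to_numpy()[sl] / 1e6

    def index_of(self, marker_id: str) -> int:
        pos = self.table.index[self.table["marker_id"] == marker_id]
        if len(pos) == 0:
            raise ValidationError(f"marker {marker_id!r} not in map")
        return int(pos[0])


@dataclass
class GenotypeMatrix:
    """Calls for one BC1 population: individuals x markers, map order."""

    individuals: list[str]
    calls: np.ndarray
    marker_map: MarkerMap
    population_label: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        if self.calls.shape[0] != len(self.individuals):
            raise ValidationError("row count does not match individual ids")
        if self.calls.shape[1] != len(self.marker_map):
            raise ValidationError("column count does not match marker map")
        bad = ~np.isin(self.calls, (REC, HET, MISSING))
        if bad.any():
            raise ValidationError("calls outside the {REC, HET, MISSING} alphabet")
        if len(self.individuals) and (self.calls == MISSING).all(axis=1).any():
            empty = [self.individuals[i] for i in np.flatnonzero((self.calls == MISSING).all(axis=1))]
            raise ValidationError(f"individual(s) with no called markers: {empty}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def chromosome_calls(self, chromosome: str) -> np.ndarray:
        return self.calls[:, self.marker_map.chromosome_slice(chromosome)]


@dataclass
class PopulationSet:
    """The four reciprocal backcross populations sharing one marker map."""

    populations: dict[str, GenotypeMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        maps = {id(g.marker_map) for g in self.populations.values()}
        if len(maps) > 1:
            tables = [g.marker_map.table for g in self.populations.values()]
            first = tables[0]
            if not all(t.equals(first) for t in tables[1:]):
                raise ValidationError("populations do not share one marker map")

    def __getitem__(self, label: str) -> GenotypeMatrix:
        return self.populations[label]

    def items(self):
        return self.populations.items()


def read_marker_table(path) -> MarkerMap:
    """Read a marker table (CSV or TSV with header id, chromosome, position).

    Column names are matched loosely (``marker_id``/``id``/``marker``,
    ``chromosome``/``chrom``/``chr``, ``pos_bp``/``pos``/``position``).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skip_blank_lines=True)
    if len(df) == 0:
        raise ValidationError("no markers")
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ValidationError(f"missing column (one of {names}) in {path}")

    mid = pick("marker_id", "id", "marker")
    chrom = pick("chromosome", "chrom", "chr")
    pos = pick("pos_bp", "pos", "position", "position_bp")
    records = list(
        zip(df[mid].astype(str), df[chrom], df[pos].astype(np.int64))
    )
    mm = MarkerMap.from_records(records)
    logger.info("read %d markers on %d chromosomes from %s", len(mm), len(mm.chromosomes), path)
    return mm


def write_marker_table(marker_map: MarkerMap, path) -> None:
    out = marker_map.table[["marker_id", "chromosome", "pos_bp"]]
    out.to_csv(path, index=False)


def read_genotype_table(path, marker_map: MarkerMap, dialect: Dialect | None = None) -> GenotypeMatrix:
    """Read a genotype score table (TSV: individual_id + one column per marker).

    Columns are re-ordered to marker-map order; every marker column in the
    file must resolve in the map.  Markers present in the map but absent from
    the file are filled as missing (with a warning).
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    file_markers = list(df.columns[1:])
    known = set(marker_map.marker_ids)
    unknown = [m for m in file_markers if m not in known]
    if unknown:
        raise ValidationError(f"marker(s) in file missing from map: {unknown}")
    absent = [m for m in marker_map.marker_ids if m not in set(file_markers)]
    if absent:
        logger.warning("%d map markers absent from %s; filled as missing", len(absent), path)
    individuals = df[id_col].astype(str).tolist()
    calls = np.full((len(individuals), len(marker_map)), MISSING, dtype=np.int8)
    col_of = {m: j for j, m in enumerate(marker_map.marker_ids)}
    for m in file_markers:
        j = col_of[m]
        column = df[m].tolist()
        for i, symbol in enumerate(column):
            try:
                calls[i, j] = dialect.encode(symbol)
            except ValidationError:
                raise ValidationError(
                    f"call symbol {symbol!r} outside dialect at individual "
                    f"{individuals[i]!r}, marker {m!r}"
                ) from None
    g = GenotypeMatrix(individuals, calls, marker_map, population_label=str(path))
    logger.info("read %d individuals x %d markers from %s", g.n_individuals, len(marker_map), path)
    return g


def write_genotype_table(genotypes: GenotypeMatrix, path, dialect: Dialect | None = None) -> None:
    """Write a genotype table re-readable by :func:`read_genotype_table`."""
    if genotypes.n_individuals == 0:
        raise ValidationError("refusing to write a table with no individuals")
    dialect = dialect or Dialect()
    decode = np.vectorize(dialect.decode, otypes=[object])
    df = pd.DataFrame(decode(genotypes.calls), columns=genotypes.marker_map.marker_ids)
    df.insert(0, "individual_id", genotypes.individuals)
    df.to_csv(path, sep="\t", index=False)


def qc_filter_individuals(
    genotypes: GenotypeMatrix, max_missing_fraction: float = 0.5
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose missing fraction strictly exceeds the threshold.

    The inequality is strict: an individual with exactly the threshold
    fraction of uncalled markers is retained.  Idempotent.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValidationError("max_missing_fraction must be in (0, 1]")
    frac = genotypes.missing_fraction()
    keep = frac <= max_missing_fraction
    discarded = [ind for ind, k in zip(genotypes.individuals, keep) if not k]
    if not keep.any():
        raise ValidationError("empty population: all individuals discarded by QC")
    if discarded:
        logger.info(
            "QC discarded %d/%d individuals (missing > %.0f%%)",
            len(discarded), genotypes.n_individuals, 100 * max_missing_fraction,
        )
    filtered = GenotypeMatrix(
        [ind for ind, k in zip(genotypes.individuals, keep) if k],
        genotypes.calls[keep],
        genotypes.marker_map,
        genotypes.population_label,
    )
    return filtered, discarded
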