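"""Core tabular types and TSV readers/writers shared by every analysis stage.

The pipeline's universal currency is an :class:`OtuTable` — a samples × OTUs
matrix of integer read counts — together with per-sample metadata (orchid
species, population, habitat class, ploidy, genome formula) and per-OTU
taxonomy (family/clade assignment and best-hit percent identity).

All tables are exchanged as UTF-8 TSV with ``.`` decimals and no quoting, so
that write→read→write round-trips are byte-stable and tests can compare files
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataValidationError",
    "DuplicateIdError",
    "TableParseError",
    "Habitat",
    "Ploidy",
    "OtuTable",
    "SampleMetadata",
    "TaxonomyRecord",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "align",
]


class DataValidationError(ValueError):
    """A table violated one of the structural invariants."""


class DuplicateIdError(DataValidationError):
    """Duplicate sample or OTU identifiers."""


class TableParseError(DataValidationError):
    """Malformed (ragged or non-numeric) table text."""


class Habitat(str, Enum):
    """Habitat classes of the sampled orchid populations."""

    MEDITERRANEAN = "mediterranean"
    PEAT_BOG = "peat_bog"
    WETLAND = "wetland"
    COASTAL = "coastal"
    ALPINE_BOREAL = "alpine_boreal"

    @classmethod
    def parse(cls, token: str) -> "Habitat":
        try:
            return cls(token)
        except ValueError:
            raise DataValidationError(
                f"unknown habitat {token!r}; expected one of "
                f"{sorted(h.value for h in cls)}"
            ) from None


class Ploidy(str, Enum):
    """Ploidy classes: diploid, triploid, tetraploid."""

    DIPLOID = "2x"
    TRIPLOID = "3x"
    TETRAPLOID = "4x"

    @classmethod
    def parse(cls, token: str) -> "Ploidy":
        try:
            return cls(token)
        except ValueError:
            raise DataValidationError(
                f"unknown ploidy {token!r}; expected one of "
                f"{sorted(p.value for p in cls)}"
            ) from None


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Samples × OTUs matrix of non-negative integer read counts.

    Rows are samples, columns OTUs; both axes carry stable, unique string
    identifiers whose order survives read→write round-trips.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise DataValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise DataValidationError("counts must be integral")
        if counts.size and counts.min() < 0:
            raise DataValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def otu_totals(self) -> np.ndarray:
        """Whole-dataset read count per OTU (column sums)."""
        return self.counts.sum(axis=0)

    def select_otus(self, keep: Sequence[str]) -> "OtuTable":
        """Column-subset to ``keep`` (order preserved from this table)."""
        keep_set = set(keep)
        idx = [j for j, o in enumerate(self.otu_ids) if o in keep_set]
        return OtuTable(
            list(self.sample_ids),
            [self.otu_ids[j] for j in idx],
            self.counts[:, idx].copy(),
        )

    def select_samples(self, keep: Sequence[str]) -> "OtuTable":
        """Row-subset/reorder to ``keep`` (order taken from ``keep``)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OtuTable(list(keep), list(self.otu_ids), self.counts[idx, :].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Attributes of one root sample: which orchid, where, in what habitat."""

    sample_id: str
    species: str
    population_id: str
    habitat: Habitat
    ploidy: Ploidy
    genome: str

    def __post_init__(self) -> None:
        if not isinstance(self.habitat, Habitat):
            self.habitat = Habitat.parse(str(self.habitat))
        if not isinstance(self.ploidy, Ploidy):
            self.ploidy = Ploidy.parse(str(self.ploidy))


@dataclass
class TaxonomyRecord:
    """Best-hit taxonomic assignment of one OTU.

    ``putative_mycorrhizal`` is derived downstream (family whitelist AND
    percent identity strictly above threshold); it defaults to False until
    :func:`dactynet.filtering.flag_mycorrhizal` sets it.
    """

    otu_id: str
    family_or_clade: str
    percent_identity: float
    putative_mycorrhizal: bool = False

    def __post_init__(self) -> None:
        self.percent_identity = float(self.percent_identity)
        if not (0.0 <= self.percent_identity <= 100.0):
            raise DataValidationError(
                f"percent_identity {self.percent_identity} for {self.otu_id!r} "
                "outside [0, 100]"
            )
        self.putative_mycorrhizal = bool(self.putative_mycorrhizal)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with labelled axes."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "distance-matrix")
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise DataValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DataValidationError("distance matrix diagonal is not zero")
        if v.size and v.min() < 0:
            raise DataValidationError("distances must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_ORIENTATIONS = ("samples_as_rows", "otus_as_rows")


def read_otu_table(path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a tab-separated count table.

    The file has one header row and one leading identifier column; by
    convention (community ecology) rows are samples, but ``orientation=
    "otus_as_rows"`` accepts the transpose.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # pandas silently renames duplicate header columns, so check the raw line
    _check_unique(header[1:], "header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"malformed table {path}: {exc}") from exc
    if df.isna().any().any():
        raise TableParseError(f"ragged or missing cells in {path}")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise DataValidationError(f"non-integer count in {path}")
    if counts.size and counts.min() < 0:
        raise DataValidationError(f"negative count in {path}")
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "otus_as_rows":
        rows, cols = cols, rows
        counts = counts.T
    return OtuTable(rows, cols, counts.astype(np.int64))


def write_otu_table(table: OtuTable, path, orientation: str = "samples_as_rows") -> None:
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    df = table.to_dataframe()
    label = "sample_id"
    if orientation == "otus_as_rows":
        df = df.T
        label = "otu_id"
    df.index.name = label
    df.to_csv(path, sep="\t", lineterminator="\n")


_META_COLUMNS = ["sample_id", "species", "population_id", "habitat", "ploidy", "genome"]


def read_metadata(path) -> list[SampleMetadata]:
    """Read the per-sample metadata TSV; enum columns are validated closed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"metadata {path} missing columns {missing}")
    if df[_META_COLUMNS].isna().any().any():
        raise TableParseError(f"missing cells in metadata {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                SampleMetadata(
                    sample_id=row.sample_id,
                    species=row.species,
                    population_id=row.population_id,
                    habitat=row.habitat,
                    ploidy=row.ploidy,
                    genome=row.genome,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(
                f"metadata row {i + 1} (sample {row.sample_id!r}): {exc}"
            ) from exc
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_metadata(records: Iterable[SampleMetadata], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "species": r.species,
                "population_id": r.population_id,
                "habitat": r.habitat.value,
                "ploidy": r.ploidy.value,
                "genome": r.genome,
            }
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


_TAX_COLUMNS = ["otu_id", "family_or_clade", "percent_identity", "putative_mycorrhizal"]


def read_taxonomy(path) -> list[TaxonomyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _TAX_COLUMNS[:3]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"taxonomy {path} missing columns {missing}")
    if df[required].isna().any().any():
        raise TableParseError(f"missing cells in taxonomy {path}")
    has_flag = "putative_mycorrhizal" in df.columns
    records = []
    for row in df.itertuples(index=False):
        flag = False
        if has_flag:
            flag = str(row.putative_mycorrhizal).strip().lower() in ("true", "1")
        records.append(
            TaxonomyRecord(
                otu_id=row.otu_id,
                family_or_clade=row.family_or_clade,
                percent_identity=float(row.percent_identity),
                putative_mycorrhizal=flag,
            )
        )
    _check_unique([r.otu_id for r in records], "OTU")
    return records


def write_taxonomy(records: Iterable[TaxonomyRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "family_or_clade": r.family_or_clade,
                "percent_identity": r.percent_identity,
                "putative_mycorrhizal": r.putative_mycorrhizal,
            }
            for r in records
        ],
        columns=_TAX_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def align(table: OtuTable, meta: Sequence[SampleMetadata]) -> OtuTable:
    """Restrict ``table`` to samples with metadata, in metadata order.

    Samples present in only one of the two inputs are dropped (and logged);
    an empty intersection is an error. Idempotent.
    """
    meta_ids = [m.sample_id for m in meta]
    _check_unique(meta_ids, "sample")
    table_set = set(table.sample_ids)
    keep = [s for s in meta_ids if s in table_set]
    if not keep:
        raise DataValidationError("no samples shared between table and metadata")
    dropped_t = sorted(table_set - set(keep))
    dropped_m = sorted(set(meta_ids) - table_set)
    if dropped_t:
        logger.warning("align: dropping %d table-only samples: %s", len(dropped_t), dropped_t)
    if dropped_m:
        logger.warning("align: dropping %d metadata-only samples: %s", len(dropped_m), dropped_m)
    return table.select_samples(keep)


def metadata_by_sample(meta: Sequence[SampleMetadata]) -> Mapping[str, SampleMetadata]:
    return {m.sample_id: m for m in meta}
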