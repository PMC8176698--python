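"""OTU count tables, sample metadata, and occupancy/salinity partitioning.

The central container is :class:`OtuTable`, an integer count matrix of shape
(n_samples, n_otus) with ordered sample and OTU identifiers and optional
taxonomy lineages. All downstream stages (diversity, assembly, networks)
consume this object. Readers/writers speak the QIIME-classic wide TSV
dialect (rows = OTUs, first column ``#OTU ID``, remaining columns samples);
orientation is auto-detected from the header token and can be forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "OccupancyClass",
    "SalinityLevel",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "filter_rare_otus",
    "rarefy",
    "classify_occupancy",
    "assign_salinity_levels",
    "subset",
]


class OtuTableError(ValueError):
    """Malformed or inconsistent OTU table input."""


@dataclass(frozen=True)
class OtuTable:
    """Samples × OTUs non-negative integer count matrix.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (rows).
    otu_ids : ordered OTU identifiers (columns).
    counts : int array of shape (n_samples, n_otus).
    taxonomy : optional mapping OTU id -> semicolon-delimited lineage.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise OtuTableError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise OtuTableError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if list(ids).count(i) > 1})
                raise OtuTableError(f"duplicate {name} ids: {dupes[:5]}")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def occupancy(self) -> np.ndarray:
        """Number of samples in which each OTU has count > 0."""
        return (self.counts > 0).sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised float matrix; all-zero samples stay zero."""
        totals = self.sample_totals.astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def presence_absence(self) -> np.ndarray:
        """Binary matrix, OTUs (species) as rows, samples as columns."""
        return (self.counts.T > 0).astype(np.uint8)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample context: date, station, salinity (permil) and env variables."""

    sample_id: str
    date: _date | None = None
    station: str = ""
    salinity: float = 0.0
    env: dict[str, float] = field(default_factory=dict)
    precipitation: float | None = None  # 7-day accumulation, mm
    wind: float | None = None  # daily average, m/s

    def __post_init__(self) -> None:
        if self.salinity < 0:
            raise ValueError(f"salinity must be >= 0, got {self.salinity}")


class OccupancyCategory(str, Enum):
    CORE = "core"
    INTERMEDIATE = "intermediate"
    SATELLITE = "satellite"


@dataclass(frozen=True)
class OccupancyClass:
    otu_id: str
    occupancy_fraction: float
    category: OccupancyCategory


@dataclass(frozen=True)
class SalinityLevel:
    sample_id: str
    level: str  # "low" | "medium" | "high"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(
    path: str | Path,
    format: str = "tsv",
    samples_as_rows: bool | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> OtuTable:
    """Read a wide-format OTU table.

    TSV dialect: by default rows are OTUs with the first column holding OTU
    ids (QIIME classic, optional ``#OTU ID`` header token). If the header's
    first token is ``#OTU ID`` the orientation is forced to OTUs-as-rows;
    otherwise ``samples_as_rows`` controls it (default False).
    """
    if format == "biom":
        raise NotImplementedError(
            "BIOM input is not supported in this build; convert to TSV "
            "(e.g. `biom convert -i table.biom -o table.tsv --to-tsv`)"
        )
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
        # tolerate a leading comment line like "# Constructed from biom file"
        while first.startswith("#") and "\t" not in first:
            first = fh.readline()
        if not first.strip():
            raise OtuTableError(f"{path}: empty or header-less file")
        header = first.rstrip("\n").split("\t")
        if header[0].strip() in ("#OTU ID", "OTU ID", "#OTU_ID"):
            samples_as_rows = False
        elif samples_as_rows is None:
            samples_as_rows = False
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise OtuTableError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            rows.append(cells)
    if not rows:
        raise OtuTableError(f"{path}: no data rows")
    row_ids = [r[0] for r in rows]
    col_ids = [h for h in header[1:]]
    values = np.empty((len(rows), len(col_ids)), dtype=np.int64)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise OtuTableError(
                    f"{path}: non-numeric count {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from exc
            if v < 0:
                raise OtuTableError(
                    f"{path}: negative count at row {row_ids[i]!r}, column {col_ids[j]!r}"
                )
            values[i, j] = int(round(v))
    if samples_as_rows:
        sample_ids, otu_ids, counts = row_ids, col_ids, values
    else:
        sample_ids, otu_ids, counts = col_ids, row_ids, values.T
    return OtuTable(
        tuple(sample_ids), tuple(otu_ids), counts,
        dict(taxonomy) if taxonomy else None,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write QIIME-classic wide TSV (rows = OTUs, ``#OTU ID`` first column)."""
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
        for j, otu in enumerate(table.otu_ids):
            fh.write(otu + "\t" + "\t".join(str(int(c)) for c in table.counts[:, j]) + "\n")


_ENV_RESERVED = {"sample_id", "date", "station", "salinity", "precipitation", "wind"}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata TSV with ISO-8601 dates.

    Required column: ``sample_id``. Recognised columns: ``date``, ``station``,
    ``salinity``, ``precipitation``, ``wind``; every other numeric column is
    collected into ``env``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise OtuTableError(f"{path}: metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise OtuTableError(f"{path}: duplicate sample_id(s): {dupes[:5]}")
    env_cols = [c for c in df.columns if c not in _ENV_RESERVED]
    out = []
    for _, row in df.iterrows():
        d = None
        if "date" in df.columns and not pd.isna(row["date"]):
            d = pd.Timestamp(row["date"]).date()
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                date=d,
                station=str(row["station"]) if "station" in df.columns else "",
                salinity=float(row["salinity"]) if "salinity" in df.columns else 0.0,
                env={c: float(row[c]) for c in env_cols if not pd.isna(row[c])},
                precipitation=float(row["precipitation"]) if "precipitation" in df.columns and not pd.isna(row["precipitation"]) else None,
                wind=float(row["wind"]) if "wind" in df.columns and not pd.isna(row["wind"]) else None,
            )
        )
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    env_keys = sorted({k for m in metadata for k in m.env})
    with open(path, "w") as fh:
        fh.write("sample_id\tdate\tstation\tsalinity\tprecipitation\twind")
        for k in env_keys:
            fh.write("\t" + k)
        fh.write("\n")
        for m in metadata:
            fh.write(
                f"{m.sample_id}\t{m.date.isoformat() if m.date else ''}\t{m.station}"
                f"\t{m.salinity:g}\t{'' if m.precipitation is None else f'{m.precipitation:g}'}"
                f"\t{'' if m.wind is None else f'{m.wind:g}'}"
            )
            for k in env_keys:
                v = m.env.get(k)
                fh.write("\t" + ("" if v is None else f"{v:g}"))
            fh.write("\n")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV: OTU id, semicolon-delimited lineage."""
    tax: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise OtuTableError(f"taxonomy line has < 2 columns: {line!r}")
            tax[parts[0]] = parts[1]
    return tax


# ---------------------------------------------------------------------------
# Filtering / rarefaction / partitioning
# ---------------------------------------------------------------------------

def filter_rare_otus(
    table: OtuTable,
    min_samples: int = 5,
    min_total_reads: int = 10,
    mode: str = "conjunctive",
) -> OtuTable:
    """Drop rare OTUs by occupancy and total-read thresholds.

    ``conjunctive`` (default) removes an OTU only when *both* occupancy <
    ``min_samples`` and total reads < ``min_total_reads``; ``disjunctive``
    removes it when either condition holds. Samples are never dropped.
    """
    if min_samples < 0 or min_total_reads < 0:
        raise ValueError("thresholds must be >= 0")
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown mode {mode!r}")
    occ = table.occupancy()
    tot = table.otu_totals
    low_occ = occ < min_samples
    low_tot = tot < min_total_reads
    remove = (low_occ & low_tot) if mode == "conjunctive" else (low_occ | low_tot)
    keep = ~remove
    otu_ids = tuple(o for o, k in zip(table.otu_ids, keep) if k)
    tax = None
    if table.taxonomy is not None:
        tax = {o: table.taxonomy[o] for o in otu_ids if o in table.taxonomy}
    return OtuTable(table.sample_ids, otu_ids, table.counts[:, keep], tax)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged warning
    (no padding). Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be > 0, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    new_counts = np.empty((int(keep.sum()), table.n_otus), dtype=np.int64)
    i = 0
    for row, k in zip(table.counts, keep):
        if not k:
            continue
        new_counts[i] = rng.multivariate_hypergeometric(row, depth)
        i += 1
    sample_ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    return OtuTable(sample_ids, table.otu_ids, new_counts, table.taxonomy)


def classify_occupancy(
    table: OtuTable,
    core_threshold: float = 0.75,
    satellite_threshold: float = 0.50,
) -> list[OccupancyClass]:
    """Partition OTUs into core (occupancy >= core_threshold), satellite
    (< satellite_threshold) and intermediate classes."""
    if not (0 <= satellite_threshold <= core_threshold <= 1):
        raise ValueError("need 0 <= satellite_threshold <= core_threshold <= 1")
    frac = table.occupancy() / table.n_samples
    out = []
    for otu, f in zip(table.otu_ids, frac):
        if f >= core_threshold:
            cat = OccupancyCategory.CORE
        elif f < satellite_threshold:
            cat = OccupancyCategory.SATELLITE
        else:
            cat = OccupancyCategory.INTERMEDIATE
        out.append(OccupancyClass(otu, float(f), cat))
    return out


def occupancy_partition(
    classes: Iterable[OccupancyClass],
) -> dict[str, list[str]]:
    """Group OTU ids by occupancy category name."""
    out: dict[str, list[str]] = {"core": [], "intermediate": [], "satellite": []}
    for c in classes:
        out[c.category.value].append(c.otu_id)
    return out


def assign_salinity_levels(
    metadata: Sequence[SampleMetadata],
    breaks: tuple[float, float] = (0.2, 2.0),
) -> list[SalinityLevel]:
    """Bin samples into low/medium/high salinity levels.

    Intervals are [0, b1], (b1, b2], (b2, inf): each break belongs to the
    lower level (right-closed convention).
    """
    b1, b2 = breaks
    if not b1 < b2:
        raise ValueError("breaks must be strictly increasing")
    out = []
    for m in metadata:
        s = m.salinity
        if s < 0:
            raise ValueError(f"negative salinity for sample {m.sample_id}")
        level = "low" if s <= b1 else ("medium" if s <= b2 else "high")
        out.append(SalinityLevel(m.sample_id, level))
    return out


def subset(
    table: OtuTable,
    sample_ids: Sequence[str] | None = None,
    otu_ids: Sequence[str] | None = None,
) -> OtuTable:
    """Order-preserving subtable over the given sample and/or OTU ids."""
    s_index = {s: i for i, s in enumerate(table.sample_ids)}
    o_index = {o: j for j, o in enumerate(table.otu_ids)}
    if sample_ids is None:
        rows = np.arange(table.n_samples)
        new_samples = table.sample_ids
    else:
        missing = [s for s in sample_ids if s not in s_index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing[:5]}")
        rows = np.array([s_index[s] for s in sample_ids], dtype=int)
        new_samples = tuple(sample_ids)
    if otu_ids is None:
        cols = np.arange(table.n_otus)
        new_otus = table.otu_ids
    else:
        missing = [o for o in otu_ids if o not in o_index]
        if missing:
            raise KeyError(f"unknown OTU id(s): {missing[:5]}")
        cols = np.array([o_index[o] for o in otu_ids], dtype=int)
        new_otus = tuple(otu_ids)
    tax = None
    if table.taxonomy is not None:
        tax = {o: table.taxonomy[o] for o in new_otus if o in table.taxonomy}
    return OtuTable(new_samples, new_otus, table.counts[np.ix_(rows, cols)], tax)
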