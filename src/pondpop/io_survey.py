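"""Readers, writers and domain records for the pond survey tables.

Three tabular inputs drive the analysis: a pond environment table (one row
per pond with the measured habitat factors and WGS84 coordinates), a capture
table (per-pond, per-season quantitative sampling counts) and a haplotype
count table (ponds x mtDNA COI haplotypes). Aligned COI sequences may be
supplied instead of the count table; :func:`counts_from_sequences` collapses
them into haplotype classes.

All tables are UTF-8 CSV with a header row; sequences travel as FASTA with
the pond encoded in the description line as ``seqID|siteID``. Coordinates are
decimal degrees and are never projected — great-circle distances are computed
downstream.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    SchemaError,
    TableParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEASONS = ("autumn", "spring")

#: Quantitative sampling effort: three minutes per shoreline zone, six zones.
DEFAULT_EFFORT_MINUTES = 18.0

_ENV_COLUMNS = (
    "site_id",
    "latitude",
    "longitude",
    "altitude",
    "surface_area",
    "perimeter",
    "vegetation_grade",
    "shoreline_vegetation_rate",
    "concrete_revetment_rate",
    "shore_gradient_mean",
    "shore_gradient_sd",
    "inflow_count",
    "outflow_count",
    "transparency_mean",
    "tn_mean",
    "nh4_mean",
    "po4_mean",
)

_RATE_COLUMNS = ("shoreline_vegetation_rate", "concrete_revetment_rate")


@dataclass(frozen=True)
class PondEnvironment:
    """One pond's measured habitat factors.

    Rates are percentages in [0, 100]; the shore gradient is the percent
    slope of the pond bed within 3 m of the shoreline. ``transparency_mean``
    is in cm and may be right-censored (the transparency tube bottomed out),
    in which case ``transparency_censored`` is True and the value stored is
    the censoring bound, never a fabricated reading.
    """

    site_id: str
    latitude: float
    longitude: float
    altitude: float
    surface_area: float
    perimeter: float
    vegetation_grade: str
    shoreline_vegetation_rate: float
    concrete_revetment_rate: float
    shore_gradient_mean: float
    shore_gradient_sd: float
    inflow_count: int
    outflow_count: int
    transparency_mean: float
    tn_mean: float
    nh4_mean: float
    po4_mean: float
    transparency_censored: bool = False

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")
        for name in _RATE_COLUMNS:
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValidationError(f"{name}={value} outside [0, 100]")
        if self.inflow_count < 0 or self.outflow_count < 0:
            raise ValidationError("waterway counts must be non-negative")


@dataclass(frozen=True)
class CaptureRecord:
    """A quantitative sampling count for one species at one pond and season."""

    site_id: str
    species: str
    season: str
    count: int
    effort_minutes: float = DEFAULT_EFFORT_MINUTES

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"season {self.season!r} must be one of {SEASONS}"
            )
        if self.count < 0:
            raise ValidationError("capture count must be non-negative")

    @property
    def density_per_minute(self) -> float:
        return self.count / self.effort_minutes


class HaplotypeCountTable:
    """Integer site x haplotype abundance matrix.

    Row sums are the number of genotyped specimens per pond; the grand total
    is the basin-wide sample size. All-zero haplotype columns are disallowed:
    a haplotype that was never observed has no business in the table.
    """

    def __init__(
        self,
        site_ids: Sequence[str],
        haplotype_ids: Sequence[str],
        counts,
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape != (len(site_ids), len(haplotype_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(site_ids)} sites x {len(haplotype_ids)} haplotypes"
            )
        if np.any(counts < 0):
            raise ValidationError("haplotype counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("haplotype counts must be integers")
            counts = counts.astype(np.int64)
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError("duplicate site_id in haplotype table")
        if len(set(haplotype_ids)) != len(haplotype_ids):
            raise ValidationError("duplicate haplotype_id in haplotype table")
        zero_cols = np.flatnonzero(counts.sum(axis=0) == 0)
        if zero_cols.size:
            names = [haplotype_ids[j] for j in zero_cols]
            raise ValidationError(f"all-zero haplotype columns: {names}")
        self.site_ids = list(map(str, site_ids))
        self.haplotype_ids = list(map(str, haplotype_ids))
        self.counts = counts.astype(np.int64)

    # -- basic queries ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def site_totals(self) -> dict[str, int]:
        return dict(zip(self.site_ids, self.counts.sum(axis=1).tolist()))

    def haplotype_totals(self) -> dict[str, int]:
        return dict(zip(self.haplotype_ids, self.counts.sum(axis=0).tolist()))

    def row(self, site_id: str) -> np.ndarray:
        return self.counts[self.site_ids.index(str(site_id))]

    def pooled(self) -> np.ndarray:
        """Basin-wide haplotype counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.site_ids, columns=self.haplotype_ids
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "HaplotypeCountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeCountTable):
            return NotImplemented
        return (
            self.site_ids == other.site_ids
            and self.haplotype_ids == other.haplotype_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeCountTable({self.n_sites} sites x "
            f"{self.n_haplotypes} haplotypes, total {self.grand_total})"
        )


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Pre-aligned DNA sequences tagged with their pond of origin."""

    records: tuple[tuple[str, str, str], ...]
    alignment_length: int

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sequence ids in alignment")
        for seq_id, _site, seq in self.records:
            if len(seq) != self.alignment_length:
                raise AlignmentError(
                    f"sequence {seq_id} has length {len(seq)}, "
                    f"expected {self.alignment_length}"
                )
            bad = set(seq.upper()) - set("ACGTN-")
            if bad:
                raise ValidationError(
                    f"sequence {seq_id} contains invalid symbols {sorted(bad)}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "AlignedSequenceSet":
        records = tuple((i, s, q.upper()) for i, s, q in records)
        if not records:
            raise ValidationError("empty sequence set")
        return cls(records, len(records[0][2]))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _float_cell(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableParseError(
            f"non-numeric value {value!r} in column {column!r}, row {row}"
        ) from None


def read_environment_table(path) -> list[PondEnvironment]:
    """Read a pond environment CSV into :class:`PondEnvironment` records.

    A ``>``-prefixed transparency (e.g. ``>100.0``) is parsed as a censored
    bound. Extra columns (locality names, accession ranges, ...) are ignored;
    missing mandatory columns raise :class:`SchemaError` naming the column.
    """
    frame = _read_csv(path)
    missing = [c for c in _ENV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"environment table missing columns: {missing}")
    ponds: list[PondEnvironment] = []
    for row_index, row in enumerate(frame.to_dict("records")):
        transparency = str(row["transparency_mean"]).strip()
        censored = transparency.startswith(">")
        bound = _float_cell(
            transparency.lstrip(">"), "transparency_mean", row_index
        )
        kwargs = {"site_id": str(row["site_id"]).strip()}
        for column in _ENV_COLUMNS[1:]:
            if column == "transparency_mean":
                continue
            if column == "vegetation_grade":
                kwargs[column] = str(row[column]).strip()
            elif column in ("inflow_count", "outflow_count"):
                kwargs[column] = int(_float_cell(str(row[column]), column, row_index))
            else:
                kwargs[column] = _float_cell(str(row[column]), column, row_index)
        ponds.append(
            PondEnvironment(
                transparency_mean=bound,
                transparency_censored=censored,
                **kwargs,
            )
        )
    return ponds


def read_capture_table(path) -> list[CaptureRecord]:
    """Read a capture CSV (site_id, species, season, count[, effort_minutes])."""
    frame = _read_csv(path)
    mandatory = ("site_id", "species", "season", "count")
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise SchemaError(f"capture table missing columns: {missing}")
    records = []
    for row_index, row in enumerate(frame.to_dict("records")):
        effort = row.get("effort_minutes")
        effort = (
            DEFAULT_EFFORT_MINUTES
            if effort is None or (isinstance(effort, float) and np.isnan(effort))
            else float(effort)
        )
        records.append(
            CaptureRecord(
                site_id=str(row["site_id"]).strip(),
                species=str(row["species"]).strip(),
                season=str(row["season"]).strip().lower(),
                count=int(_float_cell(str(row["count"]), "count", row_index)),
                effort_minutes=effort,
            )
        )
    return records


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if frame.columns.size == 0:
        raise SchemaError(f"{path} has no header row")
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def read_haplotype_table(path) -> HaplotypeCountTable:
    """Read a site x haplotype count CSV; blanks count as zero.

    All-zero haplotype columns are dropped with a warning (they carry no
    information and would break downstream dissimilarities); negative cells
    and duplicate site ids raise :class:`ValidationError`.
    """
    frame = _read_csv(path)
    if frame.columns[0] != "site_id":
        raise SchemaError("first column of a haplotype table must be 'site_id'")
    site_ids = [s.strip() for s in frame["site_id"]]
    if len(set(site_ids)) != len(site_ids):
        raise ValidationError("duplicate site_id in haplotype table")
    hap_ids = list(frame.columns[1:])
    if not hap_ids:
        raise SchemaError("haplotype table has no haplotype columns")
    counts = np.zeros((len(site_ids), len(hap_ids)), dtype=np.int64)
    for i, row in enumerate(frame.itertuples(index=False)):
        for j, cell in enumerate(row[1:]):
            cell = str(cell).strip()
            if cell == "":
                continue
            try:
                value = int(cell)
            except ValueError:
                raise TableParseError(
                    f"non-integer count {cell!r} at site {site_ids[i]}, "
                    f"haplotype {hap_ids[j]}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"negative count at site {site_ids[i]}, haplotype {hap_ids[j]}"
                )
            counts[i, j] = value
    keep = np.flatnonzero(counts.sum(axis=0) > 0)
    if keep.size < len(hap_ids):
        dropped = [hap_ids[j] for j in range(len(hap_ids)) if j not in set(keep)]
        warnings.warn(
            f"dropping all-zero haplotype columns: {dropped}", stacklevel=2
        )
        logger.warning("dropping all-zero haplotype columns: %s", dropped)
    if keep.size == 0:
        raise ValidationError("haplotype table contains no observations")
    return HaplotypeCountTable(
        site_ids, [hap_ids[j] for j in keep], counts[:, keep]
    )


def write_haplotype_table(table: HaplotypeCountTable, path) -> None:
    """Write a count table in the same CSV dialect `read_haplotype_table` reads."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["site_id", *table.haplotype_ids])
        for site, row in zip(table.site_ids, table.counts):
            writer.writerow([site, *row.tolist()])


def read_fasta(path) -> AlignedSequenceSet:
    """Read aligned FASTA with descriptions of the form ``seqID|siteID``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description.strip()
        if "|" not in name:
            raise SchemaError(
                f"FASTA description {name!r} lacks the 'seqID|siteID' form"
            )
        seq_id, site_id = name.split("|", 1)
        records.append((seq_id.strip(), site_id.strip(), str(rec.seq).upper()))
    if not records:
        raise SchemaError(f"no sequences found in {path}")
    lengths = {len(r[2]) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    return AlignedSequenceSet(tuple(records), lengths.pop())


def write_fasta(seqs: AlignedSequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{seq_id}|{site_id}", description="")
        for seq_id, site_id, seq in seqs.records
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def _compatible(seq: str, reference: str) -> bool:
    """True when the sequences agree at every position where neither is N."""
    return all(a == b or a == "N" or b == "N" for a, b in zip(seq, reference))


def counts_from_sequences(
    seqs: AlignedSequenceSet,
) -> tuple[HaplotypeCountTable, dict[str, str]]:
    """Collapse aligned sequences into haplotype classes and count per pond.

    Sequences identical over their unambiguous positions form one haplotype.
    A sequence carrying N that is compatible with more than one established
    haplotype is assigned to the most frequent of them (logged); this keeps
    the collapse deterministic. Haplotypes are relabelled H1, H2, ... in
    descending total frequency, ties broken by first occurrence, so the
    basin-dominant haplotype is always H1.
    """
    if len(seqs) == 0:
        raise ValidationError("empty sequence set")
    # pass 1: unambiguous sequences define haplotype classes
    classes: list[str] = []  # representative sequence per class
    members: list[list[int]] = []
    ambiguous: list[int] = []
    for index, (_sid, _site, seq) in enumerate(seqs.records):
        if "N" in seq:
            ambiguous.append(index)
            continue
        for k, rep in enumerate(classes):
            if seq == rep:
                members[k].append(index)
                break
        else:
            classes.append(seq)
            members.append([index])
    # pass 2: ambiguous sequences join the most frequent compatible class
    for index in ambiguous:
        seq = seqs.records[index][2]
        compatible = [k for k, rep in enumerate(classes) if _compatible(seq, rep)]
        if not compatible:
            classes.append(seq)
            members.append([index])
            continue
        best = max(compatible, key=lambda k: (len(members[k]), -k))
        if len(compatible) > 1:
            logger.info(
                "ambiguous sequence %s compatible with %d haplotypes; "
                "assigned to the most frequent",
                seqs.records[index][0],
                len(compatible),
            )
        members[best].append(index)
    # relabel by descending frequency, ties by first occurrence
    order = sorted(
        range(len(classes)), key=lambda k: (-len(members[k]), min(members[k]))
    )
    hap_ids = [f"H{rank + 1}" for rank in range(len(order))]
    hap_seqs = {hap_ids[rank]: classes[k] for rank, k in enumerate(order)}
    site_ids = list(dict.fromkeys(site for _id, site, _s in seqs.records))
    counts = np.zeros((len(site_ids), len(order)), dtype=np.int64)
    site_index = {site: i for i, site in enumerate(site_ids)}
    for rank, k in enumerate(order):
        for index in members[k]:
            counts[site_index[seqs.records[index][1]], rank] += 1
    table = HaplotypeCountTable(site_ids, hap_ids, counts)
    assert table.grand_total == len(seqs)
    return table, hap_seqs
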