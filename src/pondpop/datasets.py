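"""Bundled survey tables for the Matsumoto Basin giant water bug study.

Three small CSVs transcribed from the published survey ship with the
package so the whole pipeline is exercisable offline:

* ``matsumoto_environment.csv`` - the 33 ponds' measured habitat factors
  and WGS84 coordinates (one row per pond; transparency may be censored).
* ``matsumoto_haplotypes.csv`` - the 29 occupied ponds x 26 mtDNA COI
  haplotype count matrix (530 genotyped specimens).
* ``matsumoto_overwintering.csv`` - autumn-2015/spring-2016 quantitative
  capture counts; only the pond-level pairs reported in the survey text are
  included (13 ponds with both counts, plus the four ponds where the species
  was absent), not the full appendix capture table.

``matsumoto_diversity_printed.csv`` carries the published per-pond n, h, Hd
and Pi values for cross-checking recomputed statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assessment import OverwinteringRecord, overwintering_rate
from .io_survey import (
    HaplotypeCountTable,
    PondEnvironment,
    read_environment_table,
    read_haplotype_table,
)

__all__ = [
    "load_pond_environments",
    "load_haplotype_table",
    "load_overwintering_records",
    "load_printed_diversity",
    "data_path",
]


def data_path(name: str):
    return resources.files("pondpop.data") / name


def load_pond_environments() -> list[PondEnvironment]:
    """All 33 surveyed ponds' environment records."""
    with resources.as_file(data_path("matsumoto_environment.csv")) as path:
        return read_environment_table(path)


def load_haplotype_table() -> HaplotypeCountTable:
    """The 29-pond x 26-haplotype COI count matrix (530 specimens)."""
    with resources.as_file(data_path("matsumoto_haplotypes.csv")) as path:
        return read_haplotype_table(path)


def load_overwintering_records(
    inclusion_threshold: int = 10,
) -> list[OverwinteringRecord]:
    """Overwintering records for the ponds with published count pairs."""
    with resources.as_file(data_path("matsumoto_overwintering.csv")) as path:
        frame = pd.read_csv(path, dtype={"site_id": str})
    return [
        overwintering_rate(
            int(row.autumn_count),
            int(row.spring_count),
            inclusion_threshold,
            site_id=row.site_id,
        )
        for row in frame.itertuples(index=False)
    ]


def load_printed_diversity() -> pd.DataFrame:
    """Published per-pond n, h, Hd, Pi (as printed, for cross-checks)."""
    with resources.as_file(data_path("matsumoto_diversity_printed.csv")) as path:
        return pd.read_csv(path, dtype={"site_id": str})
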