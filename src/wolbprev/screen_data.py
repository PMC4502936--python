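"""Screen tables: data model, CSV I/O, validation and tabulation rules.

A *screen* is a PCR assay of ``n_sampled`` individuals from one host
population, ``n_infected`` of which tested positive for the symbiont.  The
table of screens (one population per row) is the unit of input for every
downstream estimator in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScreenRecord",
    "ScreenTable",
    "GroupSummary",
    "ScreenDataError",
    "read_screens",
    "write_screens",
    "species_infection_flags",
    "summarize_by",
    "pool_by_species",
    "bin_prevalences",
    "filter_countries",
    "eligible_countries",
]

#: Columns every screens CSV must provide.
REQUIRED_COLUMNS = (
    "study_id",
    "species",
    "family",
    "superfamily",
    "country",
    "n_sampled",
    "n_infected",
)

#: Optional columns, with defaults applied when absent.
OPTIONAL_COLUMNS = ("latitude", "longitude", "n_primer_sets")

#: Label for records whose grouping field is unknown ("not calculated").
NC_LABEL = "NC"

GROUP_LEVELS = ("superfamily", "family", "country", "continent")


class ScreenDataError(ValueError):
    """Malformed or invariant-violating screen data."""


@dataclass(frozen=True)
class ScreenRecord:
    """One screened population.

    Invariants: ``1 <= n_sampled``, ``0 <= n_infected <= n_sampled``, and
    latitude/longitude are either both present or both absent.
    """

    study_id: str
    species: str
    family: str
    superfamily: str
    country: str | None
    n_sampled: int
    n_infected: int
    n_primer_sets: int = 1
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.n_sampled < 1:
            raise ScreenDataError(
                f"n_sampled must be >= 1, got {self.n_sampled} "
                f"(species {self.species!r}, study {self.study_id!r})"
            )
        if not 0 <= self.n_infected <= self.n_sampled:
            raise ScreenDataError(
                f"n_infected={self.n_infected} outside [0, n_sampled={self.n_sampled}] "
                f"(species {self.species!r}, study {self.study_id!r})"
            )
        if self.n_primer_sets < 1:
            raise ScreenDataError(f"n_primer_sets must be >= 1, got {self.n_primer_sets}")
        if (self.latitude is None) != (self.longitude is None):
            raise ScreenDataError(
                "latitude and longitude must either both be present or both be absent"
            )
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ScreenDataError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ScreenDataError(f"longitude {self.longitude} outside [-180, 180]")

    @property
    def sample_prevalence(self) -> float:
        return self.n_infected / self.n_sampled


@dataclass
class ScreenTable:
    """Ordered collection of :class:`ScreenRecord`, one row per population."""

    records: list[ScreenRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScreenRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ScreenRecord:
        return self.records[i]

    @property
    def n_populations(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, n) arrays of infected and sampled counts, in row order."""
        k = np.array([r.n_infected for r in self.records], dtype=np.int64)
        n = np.array([r.n_sampled for r in self.records], dtype=np.int64)
        return k, n

    def to_frame(self) -> pd.DataFrame:
        cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=list(cols)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenDataError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for idx, row in df.iterrows():
            try:
                records.append(_record_from_row(row))
            except ScreenDataError as exc:
                raise ScreenDataError(f"row {idx}: {exc}") from exc
        return cls(records)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    v = float(value)
    return None if np.isnan(v) else v


def _record_from_row(row: Mapping) -> ScreenRecord:
    nps = row.get("n_primer_sets")
    if nps is None or (isinstance(nps, float) and np.isnan(nps)):
        nps = 1
    return ScreenRecord(
        study_id=str(row["study_id"]),
        species=str(row["species"]),
        family=str(row["family"]),
        superfamily=str(row["superfamily"]),
        country=_opt_str(row.get("country")),
        n_sampled=int(row["n_sampled"]),
        n_infected=int(row["n_infected"]),
        n_primer_sets=int(nps),
        latitude=_opt_float(row.get("latitude")),
        longitude=_opt_float(row.get("longitude")),
    )


def read_screens(path) -> ScreenTable:
    """Read a screens CSV (one population per row) into a validated table.

    Raises :class:`ScreenDataError` naming the offending column or row on
    malformed input; warns (and returns an empty table) on a header-only file.
    """
    df = pd.read_csv(path)
    table = ScreenTable.from_frame(df)
    if len(table) == 0:
        warnings.warn(f"screens file {path} contains a header but no records", stacklevel=2)
    return table


def write_screens(table: ScreenTable, path) -> None:
    """Write a table in the same CSV dialect :func:`read_screens` expects."""
    table.to_frame().to_csv(path, index=False)


def species_infection_flags(table: ScreenTable) -> dict[str, bool]:
    """Map each species to True iff any of its populations had >= 1 positive.

    This is the tabulation rule for counting a species as infected even when
    some of its populations screened entirely negative.
    """
    flags: dict[str, bool] = {}
    for r in table:
        flags[r.species] = flags.get(r.species, False) or r.n_infected >= 1
    return flags


@dataclass(frozen=True)
class GroupSummary:
    """Per-group tallies of populations, species and individuals infected."""

    group_label: str
    n_populations: int
    prop_populations_infected: float
    n_species: int
    prop_species_infected: float
    n_individuals: int
    prop_individuals_infected: float


def _continent_lookup() -> dict[str, str]:
    from .geospatial import load_centroids

    cent = load_centroids()
    return dict(zip(cent["country"], cent["continent"]))


def summarize_by(table: ScreenTable, level: str) -> list[GroupSummary]:
    """Summarize infection by superfamily, family, country or continent.

    Records lacking the grouping field (or, for ``continent``, with a country
    absent from the packaged lookup) are collected into the ``NC`` ("not
    calculated") group so that group totals always sum to the table totals.
    """
    if level not in GROUP_LEVELS:
        raise ValueError(f"unknown grouping level {level!r}; expected one of {GROUP_LEVELS}")

    if level == "continent":
        lookup = _continent_lookup()

        def label_of(r: ScreenRecord) -> str:
            return lookup.get(r.country, NC_LABEL) if r.country else NC_LABEL

    else:

        def label_of(r: ScreenRecord) -> str:
            v = getattr(r, level)
            return v if v else NC_LABEL

    groups: dict[str, list[ScreenRecord]] = {}
    for r in table:
        groups.setdefault(label_of(r), []).append(r)

    out = []
    for label in sorted(groups, key=lambda g: (g == NC_LABEL, g)):
        recs = groups[label]
        n_pop = len(recs)
        n_pop_inf = sum(r.n_infected >= 1 for r in recs)
        flags = species_infection_flags(ScreenTable(recs))
        n_ind = sum(r.n_sampled for r in recs)
        k_ind = sum(r.n_infected for r in recs)
        out.append(
            GroupSummary(
                group_label=label,
                n_populations=n_pop,
                prop_populations_infected=n_pop_inf / n_pop,
                n_species=len(flags),
                prop_species_infected=sum(flags.values()) / len(flags),
                n_individuals=n_ind,
                prop_individuals_infected=k_ind / n_ind,
            )
        )
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def pool_by_species(table: ScreenTable) -> ScreenTable:
    """Pool all populations of each species into one record (sums k and n).

    Taxonomy is carried through from the species' first record; geography is
    dropped because pooled records may span countries.
    """
    if len(table) == 0:
        raise ScreenDataError("cannot pool an empty table")
    order: list[str] = []
    acc: dict[str, dict] = {}
    for r in table:
        if r.species not in acc:
            order.append(r.species)
            acc[r.species] = {
                "study_id": r.study_id,
                "family": r.family,
                "superfamily": r.superfamily,
                "n": 0,
                "k": 0,
            }
        acc[r.species]["n"] += r.n_sampled
        acc[r.species]["k"] += r.n_infected
    records = [
        ScreenRecord(
            study_id=acc[sp]["study_id"],
            species=sp,
            family=acc[sp]["family"],
            superfamily=acc[sp]["superfamily"],
            country=None,
            n_sampled=acc[sp]["n"],
            n_infected=acc[sp]["k"],
        )
        for sp in order
    ]
    return ScreenTable(records)


def bin_prevalences(table: ScreenTable, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of sample prevalences y = k/n with upper-bound bin edges.

    Bins are (0, w], (w, 2w], ..., (1-w, 1]; a prevalence of exactly 0 is
    placed in the first bin, so the bins partition [0, 1] and the bin
    fractions sum to 1.  A prevalence exactly on an edge (e.g. 0.1 with
    w=0.1) falls in the lower bin, edges being upper bounds.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    if len(table) == 0:
        raise ScreenDataError("cannot bin an empty table")
    k, n = table.counts
    y = k / n
    # right-closed bins; shift exact zeros into the first bin
    idx = np.ceil(y / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "fraction": counts / counts.sum(),
        }
    )


def eligible_countries(table: ScreenTable, min_populations: int = 3) -> list[str]:
    """Countries screened in at least ``min_populations`` populations."""
    tally: dict[str, int] = {}
    for r in table:
        if r.country:
            tally[r.country] = tally.get(r.country, 0) + 1
    return sorted(c for c, m in tally.items() if m >= min_populations)


def filter_countries(table: ScreenTable, min_populations: int = 3) -> ScreenTable:
    """Drop records from countries with fewer than ``min_populations`` screens.

    Records with no country are dropped too (they cannot enter geographic
    tests).  The retained country set is :func:`eligible_countries`.
    """
    keep = set(eligible_countries(table, min_populations))
    return ScreenTable([r for r in table if r.country in keep])
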