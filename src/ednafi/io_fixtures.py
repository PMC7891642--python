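"""Tabular I/O and packaged reference tables.

Community data travel as a :class:`MotuTable` (samples x taxa abundance
matrix tagged with its sampling method and unit), trait assignments as a
:class:`TraitTable`, and the cross-method review of European assessment
metrics as a :class:`ReviewTable`.

Two tables are packaged as plain-CSV fixtures:

* the classification of the 198 metrics used by the 25 WFD-compliant
  national fish-based river assessment methods, by metric type and unit;
* the per cent relative abundances of the 33 fish MOTUs detected by eDNA
  metabarcoding and of the species caught by traditional electrofishing
  (TEF) in five stretches (A-E) of a large European river, together with
  the trait-guild profile of each MOTU.

Blank cells in the relative-abundance fixture are absences (0), not
missing data: the table enumerates every taxon detected by either method,
so an empty cell means "not detected by this method in this stretch".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .vocab import GUILD_VOCABULARY, METHODS

logger = logging.getLogger(__name__)

#: Tolerance on per-sample totals of percent tables (printed tables are
#: rounded to 2 decimals, so rows sum to 100 only approximately).
PERCENT_TOLERANCE = 0.5

ENV_CONTINUOUS = (
    "area_km2",        # upstream catchment area
    "slope_pm",        # river slope, per mille
    "width_m",         # river width
    "temp_site_c",     # mean annual air temperature at the site
    "temp_catchment_c",  # mean annual air temperature over the catchment
    "rainfall_mm",     # annual rainfall over the catchment
)
ENV_CATEGORICAL = ("regime", "sediment")
ENV_COLUMNS = ENV_CONTINUOUS + ENV_CATEGORICAL


class ValidationError(ValueError):
    """A table violates a structural invariant."""


@dataclass
class MotuTable:
    """Samples x taxa abundance matrix with method and unit tags.

    ``unit`` is ``"counts"`` (read counts or individual counts) or
    ``"percent"`` (rows close to 100).  ``renormalized`` records that
    percent rows were re-closed after taxa were removed — values are never
    silently rescaled on input.
    """

    data: pd.DataFrame
    method: str
    unit: str
    renormalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.unit not in ("counts", "percent"):
            raise ValidationError(f"unknown unit {self.unit!r}; expected 'counts' or 'percent'")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample identifiers: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated taxon codes: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at (sample={self.data.index[r]!r}, taxon={self.data.columns[c]!r})"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at (sample={self.data.index[r]!r}, "
                f"taxon={self.data.columns[c]!r}): {values[r, c]}"
            )
        if self.unit == "percent" and len(self.data.columns):
            totals = values.sum(axis=1)
            bad = np.abs(totals - 100.0) > PERCENT_TOLERANCE
            if bad.any():
                i = int(np.argmax(bad))
                raise ValidationError(
                    f"percent row {self.data.index[i]!r} sums to {totals[i]:.2f}, "
                    f"not 100 +/- {PERCENT_TOLERANCE}"
                )

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    def row(self, sample) -> pd.Series:
        return self.data.loc[sample]

    def with_data(self, data: pd.DataFrame, **changes) -> "MotuTable":
        return replace(self, data=data, **changes)


@dataclass(frozen=True)
class TraitTable:
    """Taxon -> guild-membership profiles over the registered vocabulary.

    ``excluded`` lists taxa deliberately left without a profile (e.g. MOTUs
    whose member species disagree ecologically); they stay visible to
    whole-assemblage richness accounting but are omitted from guild
    metrics.
    """

    profiles: Mapping[str, frozenset]
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        for taxon, guilds in self.profiles.items():
            unknown = set(guilds) - GUILD_VOCABULARY
            if unknown:
                raise ValidationError(
                    f"taxon {taxon!r} carries unregistered guild codes {sorted(unknown)}"
                )
        overlap = set(self.profiles) & set(self.excluded)
        if overlap:
            raise ValidationError(f"taxa both profiled and excluded: {sorted(overlap)}")

    def __contains__(self, taxon) -> bool:
        return taxon in self.profiles

    def __getitem__(self, taxon) -> frozenset:
        return frozenset(self.profiles[taxon])

    @property
    def taxa(self) -> list:
        return list(self.profiles)

    @property
    def vocabulary(self) -> frozenset:
        """All guild codes carried by at least one taxon."""
        out: set = set()
        for guilds in self.profiles.values():
            out |= set(guilds)
        return frozenset(out)

    def members(self, guild: str) -> frozenset:
        if guild not in GUILD_VOCABULARY:
            raise ValidationError(f"unknown guild code {guild!r}")
        return frozenset(t for t, g in self.profiles.items() if guild in g)

    def coverage(self, taxa: Iterable) -> tuple[list, list, list]:
        """Partition ``taxa`` into (profiled, excluded, unknown)."""
        profiled, excluded, unknown = [], [], []
        for t in taxa:
            if t in self.profiles:
                profiled.append(t)
            elif t in self.excluded:
                excluded.append(t)
            else:
                unknown.append(t)
        return profiled, excluded, unknown

    def merged_with(self, extra: Mapping[str, frozenset]) -> "TraitTable":
        merged = {t: frozenset(g) for t, g in self.profiles.items()}
        for t, g in extra.items():
            merged[t] = frozenset(merged.get(t, frozenset()) | set(g))
        return TraitTable(merged, self.excluded - set(extra))


@dataclass(frozen=True)
class ReviewTable:
    """Counts of assessment metrics by metric type (rows) x unit (columns)."""

    counts: pd.DataFrame
    categories: pd.Series  # metric type -> {"trait", "other"}

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("review counts must be integers")
        if (values < 0).any():
            raise ValidationError("review counts must be non-negative")
        if not self.categories.index.equals(self.counts.index):
            raise ValidationError("category labels must match metric-type rows")

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def unit_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def type_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


class Table2Fixture(NamedTuple):
    """eDNA and TEF percent tables over river stretches A-E, plus traits."""

    edna: MotuTable
    tef: MotuTable
    traits: TraitTable


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_motu_table(path, method: str, unit: str) -> MotuTable:
    """Read a samples x taxa table from CSV/TSV (delimiter by extension).

    The first column holds sample identifiers; the header row holds taxon
    codes.  Validation failures name the offending (sample, taxon) cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MotuTable(df.astype(float), method=method, unit=unit)


def write_motu_table(table: MotuTable, path) -> None:
    """Write a MotuTable to CSV/TSV; percent values keep 2 decimals."""
    path = Path(path)
    df = table.data
    if table.unit == "percent":
        df = df.round(2)
    df.to_csv(path, sep=_sep_for(path))


def read_env_table(path) -> pd.DataFrame:
    """Read an environmental-descriptor table (one row per site)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    validate_env(df)
    return df


def validate_env(env: pd.DataFrame) -> None:
    """Check the eight environmental descriptors used by the index models."""
    missing = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing:
        raise ValidationError(f"environmental table lacks columns {missing}")
    if (env["area_km2"] <= 0).any() or (env["width_m"] <= 0).any():
        raise ValidationError("catchment area and river width must be positive")
    if (env["slope_pm"] < 0).any():
        raise ValidationError("river slope must be non-negative")


def _fixture_path(name: str):
    return resources.files("ednafi.data").joinpath(name)


def load_table1_fixture() -> ReviewTable:
    """The packaged 10 x 6 metric-classification count matrix.

    Rows are metric types (five trait-guild families plus five other
    types), columns are the units metrics are expressed in.  The grand
    total is the 198 metrics of the 25 national methods.
    """
    with resources.as_file(_fixture_path("table1_metric_classification.csv")) as p:
        df = pd.read_csv(p)
    counts = df.drop(columns=["category"]).set_index("metric_type").astype(int)
    categories = df.set_index("metric_type")["category"]
    return ReviewTable(counts, categories)


def load_table2_fixture() -> Table2Fixture:
    """The packaged relative-abundance table for river stretches A-E.

    Returns the eDNA table (33 MOTU columns), the TEF table in which
    species-level sub-rows (the three *Carassius*, two *Leuciscus* and
    three Cypr_1 member species) are summed into their MOTU aggregates,
    and the trait table built from the fixture's guild column.  The TEF
    table's provenance keeps the sub-rows as printed and flags which MOTUs
    were aggregated.
    """
    with resources.as_file(_fixture_path("table2_relative_abundance.csv")) as p:
        df = pd.read_csv(p)
    stretches = ["A", "B", "C", "D", "E"]
    motu_rows = df[df["motu"].notna()].set_index("motu")
    sub_rows = df[df["motu"].isna()]

    def method_frame(tag: str, aggregate_subrows: bool) -> pd.DataFrame:
        cols = {rs: f"{rs}_{tag}" for rs in stretches}
        wide = motu_rows[list(cols.values())].fillna(0.0).T
        wide.index = [f"RS_{rs}" for rs in stretches]
        if aggregate_subrows:
            for _, row in sub_rows.iterrows():
                parent = row["parent_motu"]
                for rs, col in cols.items():
                    v = row[col]
                    if pd.notna(v):
                        wide.loc[f"RS_{rs}", parent] += v
        return wide

    edna = MotuTable(
        method_frame("eDNA", aggregate_subrows=False),
        method="eDNA",
        unit="percent",
        provenance={"source": "packaged fixture", "stretches": stretches},
    )
    aggregated = sorted(sub_rows["parent_motu"].unique())
    tef = MotuTable(
        method_frame("TEF", aggregate_subrows=True),
        method="TEF",
        unit="percent",
        provenance={
            "source": "packaged fixture",
            "aggregated_motus": aggregated,
            "species_subrows": sub_rows.set_index("species").to_dict("index"),
        },
    )
    profiles = {
        motu: frozenset(str(g).split(";"))
        for motu, g in motu_rows["guilds"].items()
        if pd.notna(g)
    }
    traits = TraitTable(profiles)
    return Table2Fixture(edna, tef, traits)


def load_boundary_config(path) -> dict:
    """Per-river-type class boundaries from YAML.

    The file maps river-type names to four strictly decreasing boundaries
    (High/Good, Good/Moderate, Moderate/Poor, Poor/Bad).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for river_type, bounds in raw.items():
        b = tuple(float(x) for x in bounds)
        if len(b) != 4 or any(b[i] <= b[i + 1] for i in range(3)):
            raise ValidationError(
                f"boundaries for {river_type!r} must be four strictly decreasing values, got {b}"
            )
        out[river_type] = b
    return out
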