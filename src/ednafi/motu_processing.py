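"""MOTU curation: discards, trait assignment, replicate pooling, closure.

Metabarcoding markers cannot always separate congeneric species, so some
MOTUs aggregate several species.  A MOTU inherits a guild profile either
when all member species share it, or when one member dominates the
reference electrofishing catch (at least 95% of the individuals caught for
the species of that MOTU); otherwise the MOTU is excluded from guild
metrics.  MOTUs whose presence reflects farming effluent, stocking or
transport from upstream lakes rather than a resident population are
discarded up front under an explicit, reason-tagged policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_fixtures import MotuTable, TraitTable, ValidationError
from .vocab import DISCARD_REASONS

logger = logging.getLogger(__name__)

#: Dominance share above which a multi-species MOTU inherits the profile
#: of its most-caught member species.
DOMINANCE_THRESHOLD = 0.95


@dataclass(frozen=True)
class DiscardPolicy:
    """Taxa to remove before analysis, each with a reason tag."""

    entries: Mapping[str, str]  # taxon -> reason

    def __post_init__(self) -> None:
        for taxon, reason in self.entries.items():
            if reason not in DISCARD_REASONS:
                raise ValidationError(
                    f"discard reason {reason!r} for {taxon!r} not in {DISCARD_REASONS}"
                )

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.entries)

    @classmethod
    def from_yaml(cls, path) -> "DiscardPolicy":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(dict(raw))


@dataclass(frozen=True)
class AssignmentRule:
    """Outcome of resolving a multi-species MOTU to a guild profile."""

    motu: str
    members: tuple
    rule: str  # "uniform-profile" | "dominant-95" | "excluded"
    profile: frozenset | None
    dominant_species: str | None = None
    dominance_share: float | None = None

    def __post_init__(self) -> None:
        if self.rule == "dominant-95":
            if self.dominance_share is None or self.dominance_share < DOMINANCE_THRESHOLD:
                raise ValidationError(
                    f"{self.motu}: dominant-95 requires a dominance share >= "
                    f"{DOMINANCE_THRESHOLD}, got {self.dominance_share}"
                )


def apply_discards(table: MotuTable, policy: DiscardPolicy) -> MotuTable:
    """Remove policy taxa from a community table.

    Percent rows are re-closed to 100 after removal (and flagged as
    renormalized); absent taxa are no-ops, logged.  Idempotent.
    """
    present = [t for t in table.taxa if t in policy.taxa]
    absent = sorted(policy.taxa - set(table.taxa))
    for t in present:
        logger.info("discarding %s (%s)", t, policy.entries[t])
    if absent:
        logger.debug("discard policy taxa not present: %s", absent)
    if not present:
        return table
    data = table.data.drop(columns=present)
    renormalized = table.renormalized
    if data.shape[1] == 0:
        warnings.warn("all taxa discarded; table is empty", stacklevel=2)
    elif table.unit == "percent":
        totals = data.sum(axis=1)
        nonzero = totals > 0
        data = data.copy()
        data.loc[nonzero] = data.loc[nonzero].div(totals[nonzero], axis=0) * 100.0
        renormalized = True
    return table.with_data(data, renormalized=renormalized)


def resolve_motu_traits(
    motu: str,
    members: Sequence[str],
    traits: TraitTable,
    reference_catch: MotuTable | None = None,
    threshold: float = DOMINANCE_THRESHOLD,
) -> AssignmentRule:
    """Assign a guild profile to a MOTU from its member species.

    If every member shares one profile the assignment is evident
    ("uniform-profile").  Otherwise, if one member accounts for at least
    ``threshold`` of the individuals caught (summed over all samples of
    ``reference_catch``) the MOTU takes that species' profile
    ("dominant-95").  Otherwise the MOTU is excluded from guild metrics.
    """
    missing = [s for s in members if s not in traits]
    if missing:
        raise ValidationError(f"{motu}: member species missing from trait table: {missing}")
    if threshold != DOMINANCE_THRESHOLD:
        logger.warning("%s: dominance threshold overridden to %.3f", motu, threshold)
    profiles = {s: traits[s] for s in members}
    distinct = set(profiles.values())
    if len(distinct) == 1:
        return AssignmentRule(motu, tuple(members), "uniform-profile", next(iter(distinct)))
    if reference_catch is not None:
        caught = {
            s: float(reference_catch.data[s].sum())
            for s in members
            if s in reference_catch.data.columns
        }
        total = sum(caught.values())
        if total > 0:
            top, top_val = max(caught.items(), key=lambda kv: (kv[1], kv[0]))
            share = top_val / total
            if share >= threshold:
                return AssignmentRule(
                    motu, tuple(members), "dominant-95", profiles[top],
                    dominant_species=top, dominance_share=share,
                )
    return AssignmentRule(motu, tuple(members), "excluded", None)


def pool_replicates(samples: MotuTable, grouping: Mapping[str, Sequence]) -> MotuTable:
    """Sum replicate count rows into pooled samples.

    ``grouping`` maps each pooled sample id to the replicate ids it pools.
    Counts are summed before any conversion to proportions, preserving
    read-count semantics for downstream model offsets.  Replicate
    provenance is retained on the result.
    """
    if samples.unit != "counts":
        raise ValidationError("replicate pooling requires a count-unit table")
    rows = {}
    for pooled_id, replicate_ids in grouping.items():
        missing = [r for r in replicate_ids if r not in samples.data.index]
        if missing:
            raise ValidationError(f"pooled sample {pooled_id!r}: unknown replicates {missing}")
        rows[pooled_id] = samples.data.loc[list(replicate_ids)].sum(axis=0)
    pooled = pd.DataFrame(rows).T
    pooled.columns = samples.data.columns
    provenance = dict(samples.provenance)
    provenance["pooled_replicates"] = {k: list(v) for k, v in grouping.items()}
    return MotuTable(pooled, method=samples.method, unit="counts", provenance=provenance)


def concat_tables(first: MotuTable, second: MotuTable) -> MotuTable:
    """Stack two tables of the same method and unit (e.g. replicate sets)."""
    if first.method != second.method:
        raise ValidationError(
            f"cannot mix methods {first.method!r} and {second.method!r} in one table"
        )
    if first.unit != second.unit:
        raise ValidationError(f"cannot mix units {first.unit!r} and {second.unit!r}")
    data = pd.concat([first.data, second.data]).fillna(0.0)
    return MotuTable(data, method=first.method, unit=first.unit)


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative values to integers summing to ``total``.

    Floors everything, then hands the leftover units to the largest
    fractional remainders (ties broken by position, deterministically).
    """
    floors = np.floor(values).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def to_relative(table: MotuTable, decimals: int = 2) -> MotuTable:
    """Convert a count table to per cent relative abundances.

    Each row is closed to exactly 100 at the output precision by
    largest-remainder rounding, so printed rows always sum to 100.00.
    """
    if table.unit != "counts":
        raise ValidationError("to_relative expects a count-unit table")
    scale = 10 ** decimals
    out = np.empty(table.data.shape, dtype=float)
    values = table.data.to_numpy(dtype=float)
    for i, sample in enumerate(table.data.index):
        row = values[i]
        total = row.sum()
        if total <= 0:
            raise ValidationError(f"sample {sample!r} has zero total abundance")
        out[i] = _largest_remainder(row / total * 100.0 * scale, 100 * scale) / scale
    data = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return MotuTable(data, method=table.method, unit="percent", provenance=dict(table.provenance))
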