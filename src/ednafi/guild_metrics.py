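"""Trait-guild community metrics and species-accumulation curves.

A guild metric summarises one sample in one of three units: the number of
present species carrying the guild (``n-species``), that count as a share
of the present species with a resolved trait profile (``rel-species``), or
the guild's share of total abundance (``rel-individuals``).  Presence for
eDNA samples means any reads after discards — no minimum-read threshold
is applied by default, though one can be passed.

Denominators of relative metrics use only taxa with resolved trait
profiles; excluded taxa are dropped with a log message so that the
denominator never drifts silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .io_fixtures import MotuTable, TraitTable, ValidationError
from .vocab import GUILD_VOCABULARY, MetricDef, index_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricValue:
    guild: str
    unit: str
    value: float
    sample_id: object = None


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean cumulative richness against sampling effort (no. campaigns)."""

    effort: tuple          # 1..n campaigns
    mean_richness: tuple
    sd_richness: tuple
    n_perm: int
    exhaustive: bool
    seed: int | None


def _resolved_presences(row: pd.Series, traits: TraitTable, min_abundance: float):
    present = row[row > min_abundance]
    profiled, excluded, unknown = traits.coverage(present.index)
    if excluded or unknown:
        logger.debug(
            "sample %s: dropping %d excluded / %d unprofiled taxa from guild metrics",
            row.name, len(excluded), len(unknown),
        )
    return present[profiled]


def guild_metric(
    row: pd.Series,
    guild: str,
    unit: str,
    traits: TraitTable,
    min_abundance: float = 0.0,
) -> MetricValue:
    """Compute one guild metric for one sample row (taxon -> abundance)."""
    if guild not in GUILD_VOCABULARY:
        raise ValidationError(f"unknown guild code {guild!r}")
    if unit not in ("n-species", "rel-species", "rel-individuals"):
        raise ValidationError(f"unknown metric unit {unit!r}")
    present = _resolved_presences(row, traits, min_abundance)
    in_guild = [t for t in present.index if guild in traits[t]]
    if unit == "n-species":
        value = float(len(in_guild))
    elif unit == "rel-species":
        if len(present) == 0:
            raise ValidationError(
                f"sample {row.name!r}: rel-species undefined with no resolved taxa present"
            )
        value = len(in_guild) / len(present)
    else:  # rel-individuals
        total = float(present.sum())
        if total <= 0:
            raise ValidationError(
                f"sample {row.name!r}: rel-individuals undefined with zero total abundance"
            )
        value = float(present[in_guild].sum()) / total
    return MetricValue(guild, unit, value, sample_id=row.name)


def index_metric_vector(
    row: pd.Series,
    traits: TraitTable,
    variant: str = "10FI",
    min_abundance: float = 0.0,
) -> list[MetricValue]:
    """The ordered metric vector of the multimetric fish index.

    ``variant="10FI"`` returns all ten metrics (four species counts, three
    species shares, three individual shares); ``variant="6FI"`` the six
    relative metrics only.
    """
    defs = index_metrics(variant)
    gaps = [m.guild for m in defs if m.guild not in traits.vocabulary]
    if gaps:
        raise ValidationError(f"trait table lacks index guilds: {gaps}")
    return [guild_metric(row, m.guild, m.unit, traits, min_abundance) for m in defs]


def metric_table(
    table: MotuTable,
    traits: TraitTable,
    variant: str = "10FI",
    min_abundance: float = 0.0,
) -> pd.DataFrame:
    """Index metrics for every sample, plus the resolved-taxa denominator.

    Returns a DataFrame indexed by sample with one column per metric and a
    ``_n_resolved`` column (number of present taxa with trait profiles),
    the binomial denominator of the species-share metrics.
    """
    defs: tuple[MetricDef, ...] = index_metrics(variant)
    rows = {}
    for sample in table.data.index:
        row = table.data.loc[sample]
        values = index_metric_vector(row, traits, variant, min_abundance)
        rec = {m.name: v.value for m, v in zip(defs, values)}
        rec["_n_resolved"] = len(_resolved_presences(row, traits, min_abundance))
        rows[sample] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def comparison_metric_table(
    table: MotuTable,
    traits: TraitTable,
    guilds,
    unit: str,
    min_abundance: float = 0.0,
) -> pd.DataFrame:
    """One column per guild of ``guilds`` in a single unit, per sample."""
    out = {
        g: [
            guild_metric(table.data.loc[s], g, unit, traits, min_abundance).value
            for s in table.data.index
        ]
        for g in guilds
    }
    return pd.DataFrame(out, index=table.data.index)


def accumulation_curve(
    campaigns: MotuTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> AccumulationCurve:
    """Species-accumulation curve over sampling campaigns.

    For each effort level k, the mean (and SD) over campaign orderings of
    the cumulative number of distinct taxa detected after k campaigns.
    When the number of distinct orderings does not exceed ``n_perm`` all
    of them are enumerated, which makes the curve exact; otherwise
    ``n_perm`` random permutations are drawn from the given seed.
    """
    if len(campaigns.data.index) < 1:
        raise ValidationError("need at least one campaign")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    presence = campaigns.data.to_numpy() > 0
    n = presence.shape[0]
    total_orderings = math.factorial(n)
    exhaustive = total_orderings <= n_perm
    if exhaustive:
        orders = list(permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_perm)]
    richness = np.empty((len(orders), n))
    for i, order in enumerate(orders):
        seen = np.zeros(presence.shape[1], dtype=bool)
        for k, idx in enumerate(order):
            seen |= presence[idx]
            richness[i, k] = seen.sum()
    return AccumulationCurve(
        effort=tuple(range(1, n + 1)),
        mean_richness=tuple(richness.mean(axis=0)),
        sd_richness=tuple(richness.std(axis=0, ddof=0)),
        n_perm=len(orders),
        exhaustive=exhaustive,
        seed=seed,
    )
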