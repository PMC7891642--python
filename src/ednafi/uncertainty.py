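"""Index uncertainty from replicate water samples and seasonal stability.

Standard eDNA sampling effort is two filtration capsules per site.  When
more capsules are available, assessing every unordered pair of capsules
maps the spatially-driven variability of the index: with ten capsules
there are 45 pairs.  By default each pair is pooled (reads summed) before
assessment, mirroring the two-capsule standard effort; averaging the two
single-capsule indices is offered as an alternative mode.  Variability is
summarised as the coefficient of variation over pair scores (sample
standard deviation, n-1 denominator) plus the fraction of pairs sharing
the modal status class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import pandas as pd

from .io_fixtures import MotuTable, ValidationError
from .motu_processing import pool_replicates
from .reference_index import classify
from .vocab import DEFAULT_BOUNDARIES


@dataclass
class UncertaintyResult:
    site: object
    n_samples: int
    pairs: list
    pair_scores: pd.Series
    pair_classes: pd.Series
    cv: float
    modal_class: str
    class_stability: float
    mode: str
    sd_definition: str = "sample standard deviation (n-1)"


@dataclass
class SeasonalReport:
    site: object
    records: pd.DataFrame  # date, score, status
    modal_class: str
    n_departures: int
    departures: list


def enumerate_pairs(sample_ids: Sequence) -> list[tuple]:
    """All C(n, 2) unordered pairs of sample ids, lexicographically ordered."""
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")
    if len(ids) < 2:
        raise ValidationError("need at least two samples to form pairs")
    return list(combinations(sorted(ids), 2))


def pairwise_index_cv(
    replicates: MotuTable,
    assess: Callable[[pd.Series], float],
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    site=None,
    mode: str = "pool",
) -> UncertaintyResult:
    """Index score and CV over all two-capsule combinations of a site.

    ``assess`` maps a pooled taxon -> read-count row to an index score in
    [0, 1].  ``mode="pool"`` sums the two capsules' reads before
    assessment (default); ``mode="average"`` averages the two
    single-capsule scores instead.
    """
    ids = list(replicates.data.index)
    if len(ids) < 3:
        raise ValidationError(
            f"CV over pairs needs >= 3 replicates (got {len(ids)}); "
            "with 2 replicates there is a single pair and no spread"
        )
    if mode not in ("pool", "average"):
        raise ValidationError(f"unknown mode {mode!r}")
    pairs = enumerate_pairs(ids)
    scores = {}
    if mode == "pool":
        grouping = {f"{a}+{b}": [a, b] for a, b in pairs}
        pooled = pool_replicates(replicates, grouping)
        for (a, b) in pairs:
            scores[(a, b)] = float(assess(pooled.data.loc[f"{a}+{b}"]))
    else:
        single = {i: float(assess(replicates.data.loc[i])) for i in ids}
        for (a, b) in pairs:
            scores[(a, b)] = (single[a] + single[b]) / 2.0
    score_series = pd.Series(scores)
    classes = score_series.map(lambda s: classify(s, boundaries)[0])
    mean = float(score_series.mean())
    sd = float(score_series.std(ddof=1))
    cv = sd / mean if mean > 0 else float("nan")
    modal = classes.value_counts().idxmax()
    stability = float((classes == modal).mean())
    return UncertaintyResult(
        site=site,
        n_samples=len(ids),
        pairs=pairs,
        pair_scores=score_series,
        pair_classes=classes,
        cv=cv,
        modal_class=modal,
        class_stability=stability,
        mode=mode,
    )


def seasonal_stability(
    series: pd.DataFrame,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    site=None,
) -> SeasonalReport:
    """Status stability of an index time series at one site.

    ``series`` has ``date`` and ``score`` columns with strictly
    increasing dates.  Each date's score is classified against the given
    (river-type specific) boundaries; the report counts departures from
    the modal class.
    """
    for col in ("date", "score"):
        if col not in series.columns:
            raise ValidationError(f"seasonal series lacks column {col!r}")
    if len(series) < 2:
        raise ValidationError("need >= 2 dates for a seasonal series")
    dates = pd.to_datetime(series["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValidationError("dates must be strictly increasing")
    records = series.copy()
    records["status"] = [classify(s, boundaries)[0] for s in series["score"]]
    modal = records["status"].value_counts().idxmax()
    departures = records.loc[records["status"] != modal, "date"].tolist()
    return SeasonalReport(
        site=site,
        records=records,
        modal_class=modal,
        n_departures=len(departures),
        departures=departures,
    )
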