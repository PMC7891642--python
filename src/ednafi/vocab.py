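"""Controlled vocabularies: trait guilds, index metrics, status classes.

Two guild families are distinguished.  The nine *comparison guilds* are the
most dissimilar species-trait categories in common use across European
fish-based river assessment methods (benthic, eurytopic, insectivorous,
omnivorous, phytophilic, potamodromous, rheophilic, tolerant, pelagic);
they drive the eDNA-versus-electrofishing representativeness analysis.
The ten *index guilds* are the guild/unit pairs entering the predictive
multimetric fish index: four expressed in number of species, three in
relative number of species and three in relative number of individuals.
"""

from __future__ import annotations

from typing import NamedTuple

#: Species-trait guilds used for the method-comparison metrics.
COMPARISON_GUILDS: frozenset[str] = frozenset(
    {"BEN", "EUR", "INS", "OMN", "PHY", "POT", "RHE", "TOL", "PEL"}
)

#: Guilds backing the multimetric index.
INDEX_GUILDS: frozenset[str] = frozenset(
    {
        "LIM-rep",     # limnophilic reproduction habitat
        "STEN",        # stenothermal (cold water)
        "OMN-i",       # omnivorous (index variant)
        "TOL-i",       # tolerant to degradation (index variant)
        "LIM-rel",     # limnophilic
        "OXY-rel",     # oxyphilous (species share)
        "INTOL-rel",   # intolerant (species share)
        "OXY-ab",      # oxyphilous (individual share)
        "HINTOL-ab",   # intolerant to habitat degradation (individual share)
        "RWSP-ab",     # running-water spawning habitat (individual share)
    }
)

GUILD_VOCABULARY: frozenset[str] = COMPARISON_GUILDS | INDEX_GUILDS

#: Measurement units for guild metrics.
UNITS = ("n-species", "rel-species", "rel-individuals")


class MetricDef(NamedTuple):
    """One metric of the multimetric index.

    ``family`` is the reference-model family ("poisson" for species counts,
    "binomial" for proportions); ``orientation`` states how the metric
    responds to anthropogenic disturbance and sets the direction of the
    EQR transform.
    """

    name: str
    guild: str
    unit: str
    family: str
    orientation: str


#: Ordered definition of the ten-metric fish index.  The first four are
#: expressed in number of species; the remaining six (the 6FI subset) in
#: relative abundance of species or individuals.
INDEX_METRICS: tuple[MetricDef, ...] = (
    MetricDef("LIM-rep", "LIM-rep", "n-species", "poisson", "increases"),
    MetricDef("STEN", "STEN", "n-species", "poisson", "decreases"),
    MetricDef("OMN-i", "OMN-i", "n-species", "poisson", "increases"),
    MetricDef("TOL-i", "TOL-i", "n-species", "poisson", "increases"),
    MetricDef("LIM-rel", "LIM-rel", "rel-species", "binomial", "increases"),
    MetricDef("OXY-rel", "OXY-rel", "rel-species", "binomial", "decreases"),
    MetricDef("INTOL-rel", "INTOL-rel", "rel-species", "binomial", "decreases"),
    MetricDef("OXY-ab", "OXY-ab", "rel-individuals", "binomial", "decreases"),
    MetricDef("HINTOL-ab", "HINTOL-ab", "rel-individuals", "binomial", "decreases"),
    MetricDef("RWSP-ab", "RWSP-ab", "rel-individuals", "binomial", "decreases"),
)

#: The six relative-abundance metrics (no species-count metrics), the
#: variant best suited to eDNA samples.
SIX_METRIC_SUBSET: tuple[MetricDef, ...] = tuple(
    m for m in INDEX_METRICS if m.unit != "n-species"
)


def index_metrics(variant: str = "10FI") -> tuple[MetricDef, ...]:
    """Return the metric definitions for an index variant ("10FI" or "6FI")."""
    if variant == "10FI":
        return INDEX_METRICS
    if variant == "6FI":
        return SIX_METRIC_SUBSET
    raise ValueError(f"unknown index variant {variant!r}; use '10FI' or '6FI'")


#: Ecological status classes, best first.
STATUS_CLASSES = ("High", "Good", "Moderate", "Poor", "Bad")

#: Default EQR class boundaries (High/Good, Good/Moderate, Moderate/Poor,
#: Poor/Bad).  Boundaries are river-type specific in operational use and
#: must be overridable; these defaults are an even partition of [0, 1].
DEFAULT_BOUNDARIES: tuple[float, float, float, float] = (0.8, 0.6, 0.4, 0.2)

#: Reasons a MOTU may be discarded before analysis.
DISCARD_REASONS = ("farmed-only", "stocking", "lentic-transport", "other")

#: Sampling methods for community tables.
METHODS = ("eDNA", "TEF")
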