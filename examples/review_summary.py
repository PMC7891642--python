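"""Summarise the cross-method review of European fish assessment metrics.

Loads the packaged classification of the 198 metrics used by the 25
WFD-compliant national fish-based river assessment methods and derives
the shares relevant to eDNA compatibility.
"""

from ednafi import load_table1_fixture, summarize_review

summary = summarize_review(load_table1_fixture())

print(f"total metrics: {summary.total}")
print(f"expressed in richness / relative abundance / relative biomass: "
      f"{summary.richness_relabund_relbiomass}")
print("unit shares (%):", summary.unit_shares)
print(f"trait-based: {summary.trait_based} ({summary.trait_based_share}%)")
print(f"taxonomy-based share: {summary.taxonomy_based_share}%")
print("guild-family shares of trait-based metrics (%):", summary.guild_family_shares)
print(f"eDNA-compatible (richness + relative abundance): "
      f"{summary.compatible} metrics, {summary.compatible_share}% of the total")

# The compatibility share is the headline figure: about 81% of the metrics
# used across Europe are expressed in units an eDNA sample can provide,
# so most national methods could in principle be adapted to eDNA data.
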