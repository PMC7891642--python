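"""Trait-guild metrics from the packaged river-stretch abundance table.

Computes the nine comparison guild metrics (richness and individual
shares) from the eDNA and electrofishing columns of the packaged
fixture, illustrating the systematic cross-method differences.
"""

from ednafi import comparison_metric_table, load_table2_fixture
from ednafi.vocab import COMPARISON_GUILDS

fixture = load_table2_fixture()
guilds = sorted(COMPARISON_GUILDS)

for unit in ("n-species", "rel-individuals"):
    edna = comparison_metric_table(fixture.edna, fixture.traits, guilds, unit)
    tef = comparison_metric_table(fixture.tef, fixture.traits, guilds, unit)
    print(f"\n=== {unit} (rows = river stretches) ===")
    print("eDNA:\n", edna.round(3))
    print("TEF:\n", tef.round(3))

# Note the pattern: pelagic (PEL) individual shares are far higher in the
# electrofishing columns (shoreline sampling overestimates sub-surface
# species), while benthic (BEN) shares are higher in the eDNA columns.
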