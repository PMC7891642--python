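# Example discard policy for a large-river basin downstream of alpine
# lakes: MOTUs whose eDNA reflects farming effluent, stocking releases or
# transport from upstream lentic waters rather than resident populations.
# These reasons are basin-specific; the policy is a documented example,
# not a default applied to other basins.
Cypr_2: farmed-only        # grass/silver carp group, farmed species only
Onc_myk: stocking          # rainbow trout, stocked for angling
Cor_spp: lentic-transport  # whitefish, carried downstream from lakes
Sal_spp: lentic-transport  # charr group, abundant in the upstream lakes
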