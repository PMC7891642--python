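metric_type,category,species_richness,relative_abundance,relative_biomass,density,biomass,expert_judgment
Habitat guilds,trait,19,12,1,2,0,0
Migratory guilds,trait,5,4,0,1,0,0
Perturbation tolerance,trait,13,15,0,1,0,0
Reproductive guilds,trait,14,13,0,0,0,0
Trophic groups,trait,8,10,0,5,0,0
Whole assemblage,other,2,7,0,2,4,0
Taxonomy-based,other,9,6,0,8,2,0
Biogeographical status,other,5,5,0,1,0,0
Health alteration,other,0,2,0,0,0,0
Length or age class,other,1,10,0,8,0,3
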