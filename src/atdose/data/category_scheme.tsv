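category	subcategory
dna_damage_and_repair	damage_response
dna_damage_and_repair	dna_repair
chromatin_organization	chromatin_organization
gene_expression_integrity	transcription
gene_expression_integrity	translation
cellular_integrity	cytoskeleton
cellular_integrity	membrane_transport
cellular_integrity	proteostasis
cell_cycle_and_differentiation	cell_cycle
cell_cycle_and_differentiation	differentiation
cell_cycle_and_differentiation	apoptosis
cell_communication	signal_transduction
cell_communication	intercellular_signaling
metabolism	carbohydrate_metabolism
metabolism	lipid_metabolism
metabolism	protein_metabolism
metabolism	energy_metabolism
stress_response	immune_response
stress_response	oxidative_stress
stress_response	other
organismic_regulation	behavior
organismic_regulation	ontogenesis
organismic_regulation	reproduction
organismic_regulation	circadian_rhythm
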