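# Offender-type rules: offense dictionary terms and generic
# offending/incarcerated population descriptors, with frozen anchors.
OFF_01	OFFENDER_TYPE	SLOT:offense_terms!
OFF_02	OFFENDER_TYPE	RX:"characteristics\s+of";SLOT:offense_terms!;LIT:"in"
OFF_03	OFFENDER_TYPE	SLOT:population_terms!
OFF_04	OFFENDER_TYPE	RX:"(?:convicted\s+of|charged\s+with|arrested\s+for|involved\s+(?:in|with))\s*(?:an?\s+)?";SLOT:offense_terms!
OFF_05	OFFENDER_TYPE	SLOT:sex_terms;RX:"with";SLOT:offense_terms!
OFF_06	OFFENDER_TYPE	RX:"(?:individuals|persons|people|populations)\s+with";SLOT:offense_terms!
OFF_07	OFFENDER_TYPE	RX:"history\s+of";SLOT:offense_terms!
OFF_08	OFFENDER_TYPE	RX:"characteristics\s+of";SLOT:population_terms!;LIT:"in"
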