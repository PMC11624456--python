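# Sex rules: the sex dictionary carries the signal; anchors add context.
SEX_01	SEX	SLOT:sex_terms!
SEX_02	SEX	SLOT:sex_terms!;LIT:"and";SLOT:sex_terms!
SEX_03	SEX	RX:"(?:incarcerated|imprisoned|detained)";SLOT:sex_terms!
SEX_04	SEX	SLOT:sex_terms!;RX:"(?:prisoners?|inmates?|offenders?|participants?)"
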