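# Nationality rules: bare demonyms, and place names behind prepositional
# anchors (precedence at standardization: countries > nationalities >
# US states > US counties > US/world cities).
NAT_01	NATIONALITY	RX:"(?:in|from|across)";SLOT:countries!
NAT_02	NATIONALITY	SLOT:nationalities!
NAT_03	NATIONALITY	RX:"(?:in|from)";SLOT:us_states!
NAT_04	NATIONALITY	RX:"(?:in|from)";SLOT:world_cities!
NAT_05	NATIONALITY	RX:"(?:in|from)";SLOT:us_cities!
NAT_06	NATIONALITY	RX:"(?:in|from)";SLOT:us_counties!
NAT_07	NATIONALITY	RX:"(?:study|studies|research|data|sample|cohort|register|registry)\s+(?:conducted\s+|drawn\s+)?(?:in|from)";SLOT:countries!
NAT_08	NATIONALITY	SLOT:countries!;RX:"(?:'s)?\s*(?:prison|correctional|justice)"
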