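# Age rules: numeric patterns (captures parsed into year bounds) and
# textual patterns over the age term dictionary.
AGE_N01	AGE	RX!:"(?<![\d.])aged?\s+\d{1,2}\s*(?:to|through|and|[-–])\s*\d{1,2}(?:[\s-]*years?)?(?:[\s-]*old)?"
AGE_N02	AGE	RX!:"(?<![\d.])\d{1,2}\s*(?:to|through|[-–])\s*\d{1,2}[\s-]*years?(?:[\s-]*old)?"
AGE_N03	AGE	RX!:"(?:between\s+)?(?<![\d.])\d{1,2}\s+and\s+\d{1,2}[\s-]*years?[\s-]*old"
AGE_N04	AGE	RX!:"(?<![\d.])aged\s+\d{1,2}(?!\d)(?!\s*(?:to|through|and|[-–]|%))"
AGE_N05	AGE	RX!:"(?:older|younger)\s+than\s+\d{1,2}(?!\d)(?:\s*years?)?(?:\s*(?:old|of\s+age))?"
AGE_N06	AGE	RX!:"(?<![\d.])\d{1,2}\s*\+(?:\s*years?)?(?:\s*old)?"
AGE_N07	AGE	RX!:"(?:under|below)\s+(?:the\s+age\s+of\s+)?\d{1,2}(?!\d)"
AGE_N08	AGE	RX!:"(?:over|above)\s+(?:the\s+age\s+of\s+)?\d{1,2}(?!\d)\s*years"
AGE_N09	AGE	RX!:"(?<![\d.])\d{1,2}[\s-]+years?[\s-]+old"
AGE_N10	AGE	RX!:"mean\s+age\s+(?:of\s+|was\s+)?\d{1,2}(?:\.\d+)?"
AGE_T01	AGE	SLOT:age_terms!
AGE_T02	AGE	SLOT:age_terms!;RX:"in\s+(?:custody|detention|prison)"
AGE_T03	AGE	RX:"(?:detained|incarcerated|imprisoned)";SLOT:age_terms!
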