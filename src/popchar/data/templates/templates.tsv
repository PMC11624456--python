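# Synthetic-corpus sentence templates. Columns:
#   characteristic <TAB> slot kind <TAB> template
# {term} is replaced by a sampled surface; the SEX "both" kind also uses
# {term2}. Templates instantiate the same lexical patterns the shipped
# rules recognise, so noise-free extraction recovers every planted span.
AGE	numeric	Participants {term} were enrolled in the program.
AGE	numeric	The trial recruited individuals {term} at baseline.
AGE	textual	The cohort consisted of {term} held in secure care.
AGE	textual	Screening covered {term} referred by the courts.
SEX	single	The sample comprised {term} recruited from three facilities.
SEX	single	Structured interviews were conducted with {term} at intake.
SEX	both	Both {term} and {term2} completed the baseline survey.
NATIONALITY	country	Data were obtained from correctional records in {term}.
NATIONALITY	country	The register covered admissions in {term} across two decades.
OFFENDER_TYPE	offense	This report describes characteristics of {term} in secure settings.
OFFENDER_TYPE	offense	Treatment outcomes among {term} were reviewed retrospectively.
OFFENDER_TYPE	population	Recidivism among {term} was assessed over the follow-up period.
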