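# Terms describing offending and incarcerated populations (seed set).
# These standardize as miscellaneous offender-type values with the
# canonical as attribute. Plural inflections expanded at load time.
offender	offender
prisoner	prisoner
inmate	inmate
detainee	detainee
convict	convict
felon	felon
criminal	criminal
remandee	remandee
cellmate	cellmate
parolee	parolee
probationer	probationer
reoffender	reoffender
recidivist	recidivist
juvenile	juvenile
delinquent	delinquent
incarcerated individual	incarcerated individual
incarcerated person	incarcerated person
incarcerated people	incarcerated person
incarcerated youth	incarcerated youth
justice-involved youth	justice-involved youth
prison population	prison population
offending population	offending population
reoffending	reoffending
detained adolescent	detained adolescent
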