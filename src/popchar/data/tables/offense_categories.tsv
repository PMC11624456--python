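# canonical offense label -> offender category [-> specific attribute]
# An empty attribute means the canonical is itself the category-level term.
sex offence	sex
rape	sex	rape
sexual assault	sex	sexual assault
sextortion	sex	sextortion
child sex abuse	child-crime-related	child sex abuse
child abuse	child-crime-related	child abuse
violent offence	violent
murder	violent	murder
homicide	violent	homicide
assault	violent	assault
robbery	violent	robbery
stalking	violent	stalking
arson	violent	arson
domestic violence	violent	domestic violence
apprehended domestic violence order	violent	apprehended domestic violence order
nonviolent offence	nonviolent
theft	nonviolent	theft
shoplifting	nonviolent	shoplifting
fraud	nonviolent	fraud
burglary	nonviolent	burglary
breach of parole	nonviolent	breach of parole
mental illness	mentally-ill
psychosis	mentally-ill	psychosis
schizophrenia	mentally-ill	schizophrenia
borderline personality disorder	mentally-ill	borderline personality disorder
personality disorder	mentally-ill	personality disorder
depression	mentally-ill	depression
bipolar disorder	mentally-ill	bipolar disorder
posttraumatic stress disorder	mentally-ill	posttraumatic stress disorder
attention deficit hyperactivity disorder	mentally-ill	attention deficit hyperactivity disorder
substance use disorder	mentally-ill	substance use disorder
intellectual disability	mentally-ill	intellectual disability
drug offence	drug-related
drug trafficking	drug-related	drug trafficking
drug possession	drug-related	drug possession
driving under the influence	drug-related	driving under the influence
ex-offender	miscellaneous	ex-offender
high risk offender	miscellaneous	high risk offender
serial offender	miscellaneous	serial offender
repeat offender	miscellaneous	repeat offender
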