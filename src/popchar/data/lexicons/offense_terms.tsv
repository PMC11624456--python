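# Offense / offender-description terms -> canonical offense label.
# Seed dictionary: singular surface forms; plural inflections are expanded
# at load time. Every canonical label must have a row in
# tables/offense_categories.tsv (validated on load).
sex offender	sex offence
sexual offender	sex offence
sex offence	sex offence
sex offense	sex offence
sex crime	sex offence
sex offending	sex offence
sexual offending	sex offence
sexual offence	sex offence
sexual offense	sex offence
rapist	rape
serial rapist	rape
rape	rape
assault with intent to commit rape	rape
sexual assault	sexual assault
sexual violence	sexual assault
sextortion	sextortion
child molester	child sex abuse
child sex abuse	child sex abuse
child sex offender	child sex abuse
child sexual abuse	child sex abuse
paedophile	child sex abuse
pedophile	child sex abuse
child abuser	child abuse
child maltreatment	child abuse
violent offender	violent offence
violent crime	violent offence
violent offence	violent offence
violent offense	violent offence
murderer	murder
murder	murder
homicide	homicide
homicide offender	homicide
manslaughter	homicide
aggravated assault	assault
assault	assault
robber	robbery
robbery	robbery
armed robbery	robbery
serial commercial robber	robbery
stalker	stalking
stalking	stalking
arsonist	arson
arson	arson
domestic violence	domestic violence
domestic violence misdemeanor	domestic violence
ADVO	apprehended domestic violence order
apprehended domestic violence order	apprehended domestic violence order
nonviolent offender	nonviolent offence
non-violent offender	nonviolent offence
nonviolent offence	nonviolent offence
nonviolent offense	nonviolent offence
theft	theft
thief	theft
shoplifter	shoplifting
shoplifting	shoplifting
fraud	fraud
fraudster	fraud
burglar	burglary
burglary	burglary
breach of parole	breach of parole
mentally ill offender	mental illness
mentally disordered offender	mental illness
psychotic	psychosis
psychotic inmate	psychosis
psychotic offender	psychosis
psychosis	psychosis
schizophrenia	schizophrenia
schizophrenic offender	schizophrenia
borderline personality disorder	borderline personality disorder
antisocial personality disorder	personality disorder
personality disorder	personality disorder
depression	depression
bipolar disorder	bipolar disorder
posttraumatic stress disorder	posttraumatic stress disorder
post-traumatic stress disorder	posttraumatic stress disorder
attention deficit hyperactivity disorder	attention deficit hyperactivity disorder
ADHD	attention deficit hyperactivity disorder
substance use disorder	substance use disorder
intellectual disability	intellectual disability
drug offender	drug offence
drug-related offender	drug offence
drug offence	drug offence
drug offense	drug offence
drug crime	drug offence
drug trafficker	drug trafficking
drug trafficking	drug trafficking
drug possession	drug possession
driving under the influence	driving under the influence
drunk driving	driving under the influence
drink driving	driving under the influence
ex-offender	ex-offender
ex-prisoner	ex-offender
high risk offender	high risk offender
high-risk offender	high risk offender
serial offender	serial offender
repeat offender	repeat offender
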