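# Textual age terms -> classification key (see the textual age table):
#   minors            -> <18
#   minors-and-18-24  -> spans <18 and 18-24 (adolescent 13-19, young 15-24)
#   unknown-adult     -> bare adult mentions (18+)
children	minors
child	minors
minors	minors
minor	minors
juveniles	minors
juvenile	minors
delinquents	minors
delinquent	minors
school children	minors
schoolchildren	minors
school-age children	minors
boys	minors
girls	minors
adolescents	minors-and-18-24
adolescent	minors-and-18-24
teen	minors-and-18-24
teens	minors-and-18-24
teenager	minors-and-18-24
teenagers	minors-and-18-24
young	minors-and-18-24
youth	minors-and-18-24
youths	minors-and-18-24
young people	minors-and-18-24
young offenders	minors-and-18-24
young adults	minors-and-18-24
adults	unknown-adult
adult	unknown-adult
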