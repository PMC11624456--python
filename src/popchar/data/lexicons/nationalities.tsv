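# Demonyms -> canonical demonym. Defunct nationalities -> miscellaneous.
# Plural noun forms ("Norwegians") are expanded at load time.
American	American
British	British
English	British
Scottish	British
Welsh	British
Australian	Australian
Canadian	Canadian
Chinese	Chinese
German	German
French	French
Swedish	Swedish
Indian	Indian
Dutch	Dutch
Italian	Italian
Japanese	Japanese
Spanish	Spanish
Brazilian	Brazilian
South African	South African
Norwegian	Norwegian
Swiss	Swiss
Finnish	Finnish
Danish	Danish
South Korean	South Korean
Korean	South Korean
New Zealander	New Zealander
Irish	Irish
Mexican	Mexican
Russian	Russian
Polish	Polish
Austrian	Austrian
Belgian	Belgian
Portuguese	Portuguese
Greek	Greek
Turkish	Turkish
Nigerian	Nigerian
Egyptian	Egyptian
Kenyan	Kenyan
Israeli	Israeli
Iranian	Iranian
Iraqi	Iraqi
Pakistani	Pakistani
Bangladeshi	Bangladeshi
Thai	Thai
Vietnamese	Vietnamese
Indonesian	Indonesian
Filipino	Filipino
Malaysian	Malaysian
Argentinian	Argentinian
Argentine	Argentinian
Chilean	Chilean
Colombian	Colombian
Peruvian	Peruvian
Hungarian	Hungarian
Czech	Czech
Slovak	Slovak
Romanian	Romanian
Bulgarian	Bulgarian
Ukrainian	Ukrainian
Croatian	Croatian
Serbian	Serbian
Slovenian	Slovenian
Estonian	Estonian
Latvian	Latvian
Lithuanian	Lithuanian
Icelandic	Icelandic
Czechoslovakian	miscellaneous
Yugoslavian	miscellaneous
Soviet	miscellaneous
Dominican	Dominican
Dominicans	Dominican
Dominicanes	Dominican
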