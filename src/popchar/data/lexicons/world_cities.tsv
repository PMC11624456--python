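# Largest world cities -> demonym of their country (seed set).
London	British
Manchester	British
Glasgow	British
Oslo	Norwegian
Stockholm	Swedish
Copenhagen	Danish
Helsinki	Finnish
Tokyo	Japanese
Osaka	Japanese
Paris	French
Lyon	French
Berlin	German
Munich	German
Hamburg	German
Madrid	Spanish
Barcelona	Spanish
Rome	Italian
Milan	Italian
Beijing	Chinese
Shanghai	Chinese
Hong Kong	Chinese
Mumbai	Indian
Delhi	Indian
Kolkata	Indian
Sydney	Australian
Melbourne	Australian
Brisbane	Australian
Perth	Australian
Toronto	Canadian
Montreal	Canadian
Vancouver	Canadian
Amsterdam	Dutch
Rotterdam	Dutch
Seoul	South Korean
Busan	South Korean
Sao Paulo	Brazilian
Rio de Janeiro	Brazilian
Moscow	Russian
Saint Petersburg	Russian
Istanbul	Turkish
Ankara	Turkish
Cairo	Egyptian
Lagos	Nigerian
Nairobi	Kenyan
Johannesburg	South African
Cape Town	South African
Zurich	Swiss
Geneva	Swiss
Vienna	Austrian
Brussels	Belgian
Lisbon	Portuguese
Athens	Greek
Warsaw	Polish
Dublin	Irish
Auckland	New Zealander
Wellington	New Zealander
Mexico City	Mexican
Buenos Aires	Argentinian
Santiago	Chilean
Bogota	Colombian
Lima	Peruvian
Bangkok	Thai
Jakarta	Indonesian
Manila	Filipino
Hanoi	Vietnamese
Karachi	Pakistani
Lahore	Pakistani
Dhaka	Bangladeshi
Tehran	Iranian
Baghdad	Iraqi
Budapest	Hungarian
Prague	Czech
Bucharest	Romanian
Kyiv	Ukrainian
Zagreb	Croatian
Belgrade	Serbian
Reykjavik	Icelandic
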