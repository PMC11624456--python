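# Country / region names -> canonical demonym. United Kingdom variants all
# standardize to one label; defunct countries -> miscellaneous.
United States	American
United States of America	American
USA	American
U.S.	American
U.S.A.	American
America	American
United Kingdom	British
Great Britain	British
Britain	British
UK	British
England	British
Scotland	British
Wales	British
Northern Ireland	British
Australia	Australian
Canada	Canadian
China	Chinese
Germany	German
France	French
Sweden	Swedish
India	Indian
Netherlands	Dutch
Italy	Italian
Japan	Japanese
Spain	Spanish
Brazil	Brazilian
South Africa	South African
Norway	Norwegian
Switzerland	Swiss
Finland	Finnish
Denmark	Danish
South Korea	South Korean
Republic of Korea	South Korean
New Zealand	New Zealander
Ireland	Irish
Mexico	Mexican
Russia	Russian
Poland	Polish
Austria	Austrian
Belgium	Belgian
Portugal	Portuguese
Greece	Greek
Turkey	Turkish
Nigeria	Nigerian
Egypt	Egyptian
Kenya	Kenyan
Israel	Israeli
Iran	Iranian
Iraq	Iraqi
Pakistan	Pakistani
Bangladesh	Bangladeshi
Thailand	Thai
Vietnam	Vietnamese
Indonesia	Indonesian
Philippines	Filipino
Malaysia	Malaysian
Argentina	Argentinian
Chile	Chilean
Colombia	Colombian
Peru	Peruvian
Hungary	Hungarian
Czech Republic	Czech
Czechia	Czech
Slovakia	Slovak
Romania	Romanian
Bulgaria	Bulgarian
Ukraine	Ukrainian
Croatia	Croatian
Serbia	Serbian
Slovenia	Slovenian
Estonia	Estonian
Latvia	Latvian
Lithuania	Lithuanian
Iceland	Icelandic
Yugoslavia	miscellaneous
Czechoslovakia	miscellaneous
Soviet Union	miscellaneous
USSR	miscellaneous
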