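# country	demonym	continent	average prisoner population 2000-2020
United States	American	North America	2120277
United Kingdom	British	Europe	88274
Australia	Australian	Oceania	30685
Canada	Canadian	North America	38321
China	Chinese	Asia	1627290
Germany	German	Europe	68437
France	French	Europe	62158
Sweden	Swedish	Europe	6510
India	Indian	Asia	385832
Netherlands	Dutch	Europe	14470
Italy	Italian	Europe	56090
Japan	Japanese	Asia	65348
Spain	Spanish	Europe	61751
Brazil	Brazilian	South America	509602
South Africa	South African	Africa	164629
Norway	Norwegian	Europe	3289
Switzerland	Swiss	Europe	6257
Finland	Finnish	Europe	3238
Denmark	Danish	Europe	3729
South Korea	South Korean	Asia	52989
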