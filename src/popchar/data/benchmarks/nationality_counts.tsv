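# Published benchmark article counts per nationality (top 20); used by the
# worked examples and the reproduction script as inputs to the
# population-adjusted ranking.
American	2922
British	993
Australian	730
Canadian	498
Chinese	371
German	340
French	281
Swedish	261
Indian	249
Dutch	249
Italian	227
Japanese	202
Spanish	193
Brazilian	162
South African	146
Norwegian	138
Swiss	135
Finnish	135
Danish	125
South Korean	94
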