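# Largest US counties (seed set) -> standardized as American.
Los Angeles County	American
Cook County	American
Harris County	American
Maricopa County	American
San Diego County	American
Orange County	American
Miami-Dade County	American
Dallas County	American
Kings County	American
Riverside County	American
Clark County	American
King County	American
Queens County	American
Tarrant County	American
Santa Clara County	American
Broward County	American
Bexar County	American
Wayne County	American
Alameda County	American
Middlesex County	American
Suffolk County	American
Philadelphia County	American
Hillsborough County	American
Sacramento County	American
Bronx County	American
Palm Beach County	American
Nassau County	American
Cuyahoga County	American
Allegheny County	American
Oakland County	American
Franklin County	American
Hennepin County	American
Fairfax County	American
Travis County	American
Contra Costa County	American
Salt Lake County	American
Montgomery County	American
Pima County	American
Fulton County	American
Mecklenburg County	American
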