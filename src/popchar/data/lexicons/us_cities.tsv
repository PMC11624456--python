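# Largest US cities (seed set) -> standardized as American.
New York City	American
Los Angeles	American
Chicago	American
Houston	American
Phoenix	American
Philadelphia	American
San Antonio	American
San Diego	American
Dallas	American
San Jose	American
Austin	American
Jacksonville	American
Fort Worth	American
Columbus	American
Charlotte	American
San Francisco	American
Indianapolis	American
Seattle	American
Denver	American
Boston	American
Nashville	American
Detroit	American
Oklahoma City	American
Portland	American
Las Vegas	American
Memphis	American
Louisville	American
Baltimore	American
Milwaukee	American
Albuquerque	American
Tucson	American
Fresno	American
Sacramento	American
Kansas City	American
Atlanta	American
Omaha	American
Miami	American
Minneapolis	American
New Orleans	American
Cleveland	American
Tampa	American
Pittsburgh	American
St. Louis	American
Cincinnati	American
Honolulu	American
Anchorage	American
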