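# US states -> standardized as American.
Alabama	American
Alaska	American
Arizona	American
Arkansas	American
California	American
Colorado	American
Connecticut	American
Delaware	American
Florida	American
Georgia	American
Hawaii	American
Idaho	American
Illinois	American
Indiana	American
Iowa	American
Kansas	American
Kentucky	American
Louisiana	American
Maine	American
Maryland	American
Massachusetts	American
Michigan	American
Minnesota	American
Mississippi	American
Missouri	American
Montana	American
Nebraska	American
Nevada	American
New Hampshire	American
New Jersey	American
New Mexico	American
New York	American
North Carolina	American
North Dakota	American
Ohio	American
Oklahoma	American
Oregon	American
Pennsylvania	American
Rhode Island	American
South Carolina	American
South Dakota	American
Tennessee	American
Texas	American
Utah	American
Vermont	American
Virginia	American
Washington	American
West Virginia	American
Wisconsin	American
Wyoming	American
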