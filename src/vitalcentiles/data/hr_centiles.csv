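age_years_midpoint,age_units_midpoint,description,c1,c2.5,c5,c10,c25,c50,c75,c90,c95,c97.5,c99
0.042,0.5 months,<1 month,106,114,121,128,140,153,165,177,184,191,198
0.125,1.5 months,1 to <2 months,112,119,126,133,144,156,168,180,187,194,202
0.208,2.5 months,2 to < 3 months,108,115,121,128,139,151,163,176,184,192,201
0.292,3.5 months,3 to <4 months,105,111,117,124,135,147,160,173,182,190,200
0.375,4.5 months,4 to <5 months,102,109,115,121,133,145,159,172,181,190,200
0.458,5.5 months,5 to <6 months,101,107,113,120,131,144,158,173,182,190,201
0.542,6.5 months,6 to <7 months,100,106,111,118,130,143,158,173,182,191,201
0.625,7.5 months,7 to <8 months,98,104,110,117,128,142,157,172,182,190,201
0.708,8.5 months,8 to <9 months,97,103,109,115,127,141,157,172,182,190,201
0.792,9.5 months,9 to <10 months,96,102,107,114,126,141,157,172,182,190,201
0.875,10.5 months,10 to <11 months,95,101,106,113,125,140,157,172,182,191,201
0.958,11.5 months,11 to <12 months,94,100,106,112,125,140,157,173,183,191,201
1.042,12.5 months,12 to <13 months,93,100,105,112,124,140,158,174,183,192,202
1.125,13.5 months,13 to <14 months,93,99,105,112,124,140,158,174,184,193,203
1.208,14.5 months,14 to <15 months,92,98,104,111,124,140,158,174,184,193,204
1.292,15.5 months,15 to <16 months,92,98,103,110,123,140,158,174,184,193,204
1.375,16.5 months,16 to <17 months,91,97,103,110,123,139,157,174,184,193,203
1.458,17.5 months,17 to <18 months,90,96,102,109,122,138,157,173,183,192,203
1.542,18.5 months,18 to <19 months,89,95,101,108,121,137,156,172,182,191,202
1.625,19.5 months,19 to <20 months,89,95,100,107,120,136,154,171,181,190,201
1.708,20.5 months,20 to <21 months,88,94,99,106,119,135,153,170,180,189,200
1.792,21.5 months,21 to <22 months,87,93,98,105,118,134,152,169,179,188,198
1.875,22.5 months,22 to <23 months,86,92,98,104,117,133,151,167,178,187,197
1.958,23.5 months,23 months to <2 years,86,92,97,104,116,132,150,166,176,185,196
2.5,2.5 years,2 to <3 years,82,88,93,99,111,126,143,159,169,178,189
3.5,3.5 years,3 to <4 years,77,82,87,93,103,118,133,149,158,167,177
4.5,4.5 years,4 to <5 years,73,78,82,88,98,112,127,142,152,160,170
5.5,5.5 years,5 to <6 years,70,75,79,84,94,107,122,137,146,154,165
6.5,6.5 years,6 to <7 years,67,71,76,81,90,103,118,132,141,149,160
7.5,7.5 years,7 to <8 years,65,69,73,78,87,99,113,128,137,145,155
8.5,8.5 years,8 to <9 years,63,67,71,76,85,97,110,124,133,141,152
9.5,9.5 years,9 to <10 years,62,66,70,74,83,94,107,121,130,138,149
10.5,10.5 years,10 to <11 years,60,64,68,73,81,92,105,118,127,136,146
11.5,11.5 years,11 to <12 years,59,63,67,71,79,90,103,116,125,133,143
12.5,12.5 years,12 to <13 years,57,61,65,69,77,88,100,113,122,130,140
13.5,13.5 years,13 to <14 years,56,59,63,67,75,86,98,111,119,127,138
14.5,14.5 years,14 to <15 years,54,58,62,66,74,84,96,109,117,125,135
15.5,15.5 years,15 to <16 years,53,57,61,65,73,84,96,108,116,124,134
16.5,16.5 years,16 to <17 years,53,57,60,65,73,83,96,108,116,124,133
17.5,17.5 years,17 to <18 years,53,57,60,65,73,84,96,109,117,124,134
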