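age_years_midpoint,age_units_midpoint,description,c1,c2.5,c5,c10,c25,c50,c75,c90,c95,c97.5,c99
0.042,0.5 month,<1 month,19,22,24,27,33,39,47,54,59,64,69
0.125,1.5 months,1 to <2 month,20,22,24,27,32,38,45,53,58,63,69
0.208,2.5 months,2 to <3 month,19,21,23,26,30,37,44,52,58,63,70
0.292,3.5 months,3 to <4 month,19,21,23,25,29,35,42,51,57,63,71
0.375,4.5 months,4 to <5 month,18,20,22,24,28,34,41,49,56,62,71
0.458,5.5 months,5 to <6 month,18,20,21,23,27,33,40,48,54,61,71
0.542,6.5 months,6 to <7 month,18,20,21,23,27,32,38,46,53,60,70
0.625,7.5 months,7 to <8 month,18,19,21,23,26,31,37,45,51,58,69
0.708,8.5 months,8 to <9 month,18,19,20,22,26,30,36,44,50,57,67
0.792,9.5 months,9 to <10 month,17,19,20,22,25,30,35,43,49,56,66
0.875,10.5 months,10 to <11 month,17,19,20,22,25,29,35,42,48,55,65
0.958,11.5 months,11 to <12 month,17,19,20,21,24,29,34,41,47,54,64
1.042,12.5 months,12 to <13 month,17,18,20,21,24,28,34,40,46,53,64
1.125,13.5 months,13 to <14 month,17,18,20,21,24,28,33,40,46,52,63
1.208,14.5 months,14 to <15 month,17,18,20,21,24,28,33,39,45,51,62
1.292,15.5 months,15 to <16 month,17,18,19,21,24,27,32,39,44,51,62
1.375,16.5 months,16 to <17 month,17,18,19,21,23,27,32,38,44,50,61
1.458,17.5 months,17 to <18 month,17,18,19,21,23,27,32,38,43,50,61
1.542,18.5 months,18 to <19 month,17,18,19,20,23,27,31,37,43,49,60
1.625,19.5 months,19 to <20 month,17,18,19,20,23,26,31,37,42,48,59
1.708,20.5 months,20 to <21 month,16,18,19,20,23,26,30,36,41,48,59
1.792,21.5 months,21 to <22 month,16,18,19,20,23,26,30,36,41,47,58
1.875,22.5 months,22 to <23 month,16,18,19,20,22,26,30,35,40,47,58
1.958,23.5 months,23 month to <2 years,16,17,19,20,22,25,29,35,40,46,57
2.5,2.5 years,2 to <3 years,16,17,18,19,21,24,28,33,37,43,53
3.5,3.5 years,3 to <4 years,15,16,17,18,20,23,26,30,34,38,47
4.5,4.5 years,4 to <5 years,15,16,17,18,20,22,25,28,31,35,43
5.5,5.5 years,5 to <6 years,14,16,17,18,19,21,24,27,30,33,39
6.5,6.5 years,6 to <7 years,14,15,16,17,19,21,23,26,28,31,37
7.5,7.5 years,7 to <8 years,14,15,16,17,18,20,22,25,27,30,35
8.5,8.5 years,8 to <9 years,14,15,16,17,18,20,22,25,27,29,33
9.5,9.5 years,9 to <10 years,13,15,15,16,18,20,22,24,26,28,32
10.5,10.5 years,10 to <11 years,13,14,15,16,18,19,21,23,25,28,31
11.5,11.5 years,11 to <12 years,13,14,15,16,17,19,21,23,25,27,30
12.5,12.5 years,12 to <13 years,13,14,15,16,17,19,20,22,24,26,29
13.5,13.5 years,13 to <14 years,13,14,15,15,17,18,20,22,24,25,28
14.5,14.5 years,14 to <15 years,13,14,14,15,17,18,20,22,23,25,28
15.5,15.5 years,15 to <16 years,13,14,14,15,17,18,20,22,23,25,27
16.5,16.5 years,16 to <17 years,12,14,14,15,17,18,20,21,23,24,27
17.5,17.5 years,17 to <18 years,12,14,14,15,16,18,19,21,23,24,27
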