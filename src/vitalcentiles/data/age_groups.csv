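description,count,pct
<1 month,12860,1.1
1 to <2 months,13016,1.1
2 to <3 months,13204,1.1
3 to <4 months,11255,0.9
4 to <5 months,11846,1.0
5 to <6 months,12317,1.0
6 to <7 months,12895,1.1
7 to <8 months,13354,1.1
8 to <9 months,13580,1.1
9 to <10 months,13349,1.1
10 to <11 months,13234,1.1
11 to <12 months,13002,1.1
12 to <13 months,13016,1.1
13 to <14 months,12078,1.0
14 to <15 months,11548,1.0
15 to <16 months,11115,0.9
16 to <17 months,10805,0.9
17 to <18 months,10351,0.9
18 to <19 months,10012,0.8
19 to <20 months,9476,0.8
20 to <21 months,9085,0.8
21 to <22 months,9011,0.7
22 to <23 months,8878,0.7
23 to <2 years,8716,0.7
2 to <3 years,93406,7.8
3 to <4 years,82813,6.9
4 to <5 years,74328,6.2
5 to <6 years,68517,5.7
6 to <7 years,59316,4.9
7 to <8 years,50664,4.2
8 to <9 years,46448,3.9
9 to <10 years,44818,3.7
10 to <11 years,44093,3.7
11 to <12 years,43225,3.6
12 to <13 years,42813,3.6
13 to <14 years,45766,3.8
14 to <15 years,50007,4.2
15 to <16 years,53940,4.5
16 to <17 years,59621,5.0
17 to <18 years,65264,5.4
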