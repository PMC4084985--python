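year,tag_id,total_length_mm,sex,dd_a,first_a,last_a,tp_a,ri_a,dd_ss,first_ss,last_ss,tp_ss,ri_ss,multiyear,censored
2007,1,642,M,43,2007-06-04,2007-08-19,77,55.8,29,2007-07-04,2007-08-19,47,61.7,0,0
2007,2,640,F,2,2007-06-04,2007-06-08,5,40.0,,,,,,0,0
2007,3,609,M,30,2007-06-05,2007-08-09,66,45.5,10,2007-06-05,2007-08-02,59,16.9,0,0
2007,4,570,F,20,2007-06-05,2007-07-21,47,42.6,12,2007-06-21,2007-07-21,31,38.7,0,0
2007,5,530,M,28,2007-06-11,2007-08-04,55,50.9,1,2007-06-11,2007-06-11,1,100.0,0,0
2007,6,535,F,18,2007-06-11,2007-08-13,64,28.1,14,2007-06-11,2007-08-13,64,21.9,0,0
2007,7,555,M,10,2007-06-14,2007-06-28,15,66.7,3,2007-06-14,2007-06-25,12,25.0,0,0
2007,8,581,M,40,2007-06-14,2007-08-17,65,61.5,23,2007-06-14,2007-08-17,65,35.4,0,0
2007,9,547,M,57,2007-06-14,2007-08-15,63,90.5,37,2007-06-14,2007-08-13,61,60.7,0,0
2007,10,554,M,81,2007-06-14,2007-09-17,96,84.4,63,2007-06-14,2007-09-16,95,66.3,0,0
2007,11,540,M,22,2007-06-14,2007-07-10,27,81.5,12,2007-06-18,2007-07-09,22,54.5,0,0
2007,12,546,M,61,2007-06-14,2007-08-20,68,89.7,39,2007-06-14,2007-08-18,66,59.1,0,0
2007,13,495,M,72,2007-06-14,2007-09-19,98,73.5,40,2007-06-14,2007-09-18,97,41.2,0,0
2007,14,659,F,13,2007-06-30,2007-08-13,45,28.9,2,2007-07-02,2007-07-31,30,6.7,0,0
2007,15,792,F,10,2007-06-18,2007-08-30,74,13.5,10,2007-06-18,2007-08-30,74,13.5,0,0
2007,16,684,F,7,2007-06-19,2007-08-11,54,13.0,7,2007-06-19,2007-08-11,54,13.0,0,0
2007,17,618,F,26,2007-06-20,2007-08-22,64,40.6,17,2007-06-29,2007-08-19,52,32.7,0,0
2007,18,659,F,17,2007-06-29,2007-07-30,32,53.1,8,2007-06-30,2007-07-30,31,25.8,0,0
2007,19,584,F,9,2007-06-19,2007-07-14,26,34.6,3,2007-06-19,2007-07-01,13,23.1,0,0
2007,20,575,F,30,2007-06-19,2007-08-12,55,54.5,18,2007-06-19,2007-08-02,45,40.0,0,0
2007,21,769,F,14,2007-06-25,2007-08-28,65,21.5,9,2007-07-04,2007-08-28,56,16.1,1,0
2007,22,660,F,30,2007-06-25,2007-09-15,83,36.1,25,2007-06-25,2007-09-15,83,30.1,1,0
2007,23,575,F,27,2007-06-04,2007-09-14,103,26.2,6,2007-07-13,2007-09-14,64,9.4,1,0
2007,24,579,M,79,2007-06-04,2007-09-17,106,74.5,59,2007-06-13,2007-09-12,92,64.1,1,0
2007,25,689,M,104,2007-06-05,2007-09-20,108,96.3,102,2007-06-05,2007-09-20,108,94.4,1,0
2007,26,745,F,21,2007-06-05,2007-09-12,100,21.0,10,2007-07-01,2007-09-12,74,13.5,1,0
2007,27,759,M,108,2007-06-05,2007-09-20,108,100.0,54,2007-06-12,2007-09-20,101,53.5,1,0
2007,29,681,F,101,2007-06-11,2007-09-20,102,99.0,100,2007-06-11,2007-09-20,102,98.0,1,0
2007,30,559,M,29,2007-06-18,2007-07-23,36,80.6,18,2007-06-29,2007-07-22,24,75.0,1,0
2007,31,625,M,7,2007-06-25,2007-08-06,43,16.3,4,2007-07-06,2007-08-06,32,12.5,1,0
2008,22,660,F,23,2008-05-24,2008-09-02,102,22.5,16,2008-05-25,2008-08-29,97,16.5,1,0
2008,23,575,F,26,2008-05-24,2008-09-02,102,25.5,20,2008-05-24,2008-09-02,102,19.6,1,0
2008,24,579,M,63,2008-05-11,2008-08-19,101,62.4,53,2008-05-21,2008-08-19,91,58.2,1,0
2008,25,689,M,178,2008-03-21,2008-09-19,183,97.3,176,2008-03-21,2008-09-19,183,96.2,1,0
2008,26,745,F,16,2008-03-25,2008-08-01,130,12.3,12,2008-03-25,2008-07-22,120,10.0,1,0
2008,27,759,M,176,2008-03-21,2008-09-20,184,95.7,101,2008-03-23,2008-09-19,181,55.8,1,0
2008,29,681,F,110,2008-05-22,2008-09-19,121,90.9,97,2008-05-22,2008-09-18,120,80.8,1,0
2008,30,559,M,40,2008-05-19,2008-07-22,65,61.5,36,2008-05-21,2008-07-22,63,57.1,1,0
2008,31,625,M,1,2008-07-11,2008-07-11,1,,,,,,,1,0
2009,22,660,F,30,2009-05-18,2009-09-06,112,26.8,28,2009-05-18,2009-08-25,100,28.0,1,0
2009,23,575,F,72,2009-04-26,2009-09-17,145,49.7,27,2009-06-06,2009-09-05,92,29.3,1,0
2009,24,579,M,76,2009-05-17,2009-09-07,114,66.7,65,2009-05-17,2009-09-07,114,57.0,1,0
2009,25,689,M,180,2009-03-21,2009-09-20,184,97.8,180,2009-03-21,2009-09-20,184,97.8,1,0
2009,26,745,F,,2009-04-01,,,,,2009-06-08,,,,1,1
2009,27,759,M,178,2009-03-21,2009-09-20,184,96.7,145,2009-03-23,2009-09-18,180,80.6,1,0
2009,30,559,M,,2009-05-08,,,,,2009-05-08,,,,1,1
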