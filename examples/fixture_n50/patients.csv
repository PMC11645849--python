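patient_id,age,female,diabetes_duration,death_time,censor_time,administrative_end_time,hist_IHD,hist_MI,hist_STROKE,hist_CHF,hist_BLINDNESS,hist_AMPUTATION,hist_RENAL_FAILURE,hist_ULCER
1,70.2,1,7.2,,2.683669078590648,2.683669078590648,1,0,0,0,0,1,0,0
2,75.1,1,15.2,,2.548970986751261,2.673669923794431,1,0,0,0,0,0,0,0
3,71.2,1,2.7,,3.2636103778232286,4.287994423621734,0,0,0,0,0,0,0,0
4,54.2,0,11.6,,3.0804808893095563,3.0804808893095563,0,0,0,0,0,0,0,0
5,50.9,1,9.8,,4.095343397557375,4.095343397557375,0,0,0,1,1,0,0,0
6,62.5,0,8.8,,1.1640839588051304,3.726611138631431,0,1,0,0,0,0,0,0
7,68.9,1,48.3,,2.7034299429472437,2.7034299429472437,0,0,0,0,0,0,0,1
8,66.1,0,2.7,,3.310999909432684,3.310999909432684,0,0,0,0,0,0,0,0
9,76.5,0,11.8,,3.5998262788076256,3.5998262788076256,1,0,0,0,0,0,0,1
10,68.0,0,12.5,,3.0442971573577413,3.0442971573577413,0,0,0,0,0,0,0,0
11,67.1,0,15.9,,2.6874385222650274,4.266532150697863,0,1,1,0,0,0,0,0
12,56.1,0,4.6,,3.5793014907554346,3.5793014907554346,0,1,0,0,0,0,0,0
13,53.1,1,9.1,,3.4116157974110877,3.4116157974110877,0,0,0,1,0,0,0,0
14,73.9,1,4.9,,3.4542254233210072,3.4542254233210072,0,1,0,0,0,0,0,0
15,62.4,0,11.1,,2.598357918981212,2.598357918981212,0,1,0,1,0,0,0,0
16,68.5,0,13.5,,3.392512790643969,3.392512790643969,1,0,0,1,0,0,0,0
17,51.0,1,13.2,,2.7953016383087674,2.7953016383087674,0,0,1,0,0,0,0,0
18,58.5,1,10.7,,3.1701499765546712,3.1701499765546712,1,0,0,0,0,0,0,0
19,51.7,1,13.4,,3.3833160497886343,3.3833160497886343,1,0,0,0,0,0,0,0
20,55.8,1,13.3,,2.745972758616238,2.745972758616238,0,0,0,0,1,0,0,0
21,69.2,1,15.3,,2.6892555103340596,2.6892555103340596,0,0,0,0,0,0,0,0
22,50.2,0,12.2,0.5,3.421118936767791,3.421118936767791,1,1,1,1,0,0,0,0
23,57.7,0,4.1,,2.5971076941612106,2.5971076941612106,0,0,0,0,0,0,0,0
24,63.3,1,7.4,0.5,1.0629084180720287,3.618017570935752,1,1,0,0,0,0,0,0
25,56.7,0,14.8,,2.8401371120453023,2.8401371120453023,0,0,0,0,0,0,0,0
26,60.0,0,6.9,,4.300248159382154,4.300248159382154,1,0,0,0,0,0,0,0
27,60.2,0,7.4,,4.392296145932049,4.392296145932049,1,0,0,0,0,0,0,0
28,65.3,1,12.8,,4.3130652004696035,4.3130652004696035,1,0,0,1,0,0,0,0
29,58.5,0,11.7,,3.1942048500455655,3.1942048500455655,0,0,0,0,0,0,0,0
30,64.2,1,20.5,,3.132352358447956,3.132352358447956,1,1,0,0,0,0,0,0
31,62.5,0,16.3,,4.069532036619753,4.069532036619753,0,0,0,0,0,0,0,0
32,65.4,0,9.2,,3.483758204568211,3.483758204568211,1,0,1,0,0,0,0,0
33,63.8,1,12.9,2.5,4.189860188811079,4.189860188811079,0,1,0,1,0,0,0,0
34,75.3,0,2.2,,0.2070457070132841,3.011151008610555,1,1,0,0,0,0,0,0
35,56.7,1,7.4,,3.27680306444579,3.27680306444579,1,1,0,0,0,0,0,0
36,71.6,0,11.0,1.5,3.0563390972339035,3.0563390972339035,1,0,0,0,0,0,0,0
37,58.8,1,2.9,,3.281048990408645,3.281048990408645,1,1,0,0,0,0,0,0
38,54.3,1,9.9,,3.666424963417212,3.666424963417212,0,0,1,0,0,0,0,0
39,71.7,1,14.0,,4.458042868990203,4.458042868990203,0,0,0,1,0,0,0,0
40,58.5,1,22.3,2.5,3.511838219113926,3.511838219113926,1,0,0,1,0,0,0,0
41,58.9,0,15.3,,3.0113860692107477,3.0113860692107477,0,0,0,1,0,0,0,0
42,50.9,1,37.2,,3.3767956518952476,3.3767956518952476,0,0,0,1,0,0,0,0
43,45.2,0,30.0,,4.005330548307162,4.005330548307162,0,0,0,0,0,0,0,0
44,67.1,1,4.5,,4.173879691068704,4.173879691068704,0,0,0,0,0,0,0,0
45,52.7,0,10.5,2.5,3.125243545760842,3.125243545760842,1,1,0,0,0,0,0,0
46,68.2,0,10.9,,3.384455692405688,3.384455692405688,0,0,0,0,0,0,0,0
47,76.8,1,12.7,,3.5019656049400565,3.5019656049400565,1,1,0,0,0,0,0,0
48,61.1,0,8.5,,3.654030190184492,3.654030190184492,0,1,0,0,0,0,0,0
49,53.0,1,17.3,,0.6393451078143656,3.8626546490803317,0,1,0,0,0,0,0,0
50,65.2,1,18.8,,1.3709777823284144,2.928029678558837,0,0,0,0,0,0,0,0
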