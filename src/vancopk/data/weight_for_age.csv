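age_years,median_weight_kg
0.0,3.35
0.25,6.00
0.5,7.50
0.75,8.60
1.0,9.45
1.5,10.70
2.0,12.00
3.0,14.20
4.0,16.20
5.0,18.20
6.0,20.40
7.0,22.90
8.0,25.70
9.0,28.70
10.0,32.00
11.0,35.70
12.0,40.00
13.0,45.00
14.0,49.80
15.0,54.00
16.0,57.50
17.0,60.00
18.0,62.00
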