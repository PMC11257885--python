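age_years,sex,weight_median_kg,weight_cv,height_median_cm,height_cv
0.0,M,3.35,0.12,49.9,0.035
0.04,M,3.80,0.12,51.1,0.035
0.0833,M,4.50,0.12,54.7,0.035
0.1667,M,5.60,0.12,58.4,0.035
0.25,M,6.40,0.12,61.4,0.035
0.375,M,7.00,0.12,64.2,0.035
0.5,M,7.90,0.12,67.6,0.035
0.75,M,8.90,0.12,72.0,0.035
1.0,M,9.60,0.12,75.7,0.035
1.5,M,10.90,0.12,82.3,0.035
2.0,M,12.20,0.12,87.8,0.035
3.0,M,14.30,0.12,96.1,0.035
4.0,M,16.30,0.12,103.3,0.035
5.0,M,18.30,0.13,110.0,0.035
6.0,M,20.50,0.13,116.0,0.035
8.0,M,25.40,0.14,128.0,0.035
10.0,M,31.90,0.15,138.4,0.035
12.0,M,39.80,0.15,149.1,0.035
14.0,M,50.80,0.15,163.8,0.035
16.0,M,60.80,0.14,173.4,0.035
18.0,M,66.90,0.14,176.8,0.035
0.0,F,3.20,0.12,49.1,0.035
0.04,F,3.60,0.12,50.3,0.035
0.0833,F,4.20,0.12,53.7,0.035
0.1667,F,5.10,0.12,57.1,0.035
0.25,F,5.80,0.12,59.8,0.035
0.375,F,6.40,0.12,62.5,0.035
0.5,F,7.30,0.12,65.7,0.035
0.75,F,8.20,0.12,70.1,0.035
1.0,F,8.90,0.12,74.0,0.035
1.5,F,10.20,0.12,80.7,0.035
2.0,F,11.50,0.12,86.4,0.035
3.0,F,13.90,0.12,95.1,0.035
4.0,F,16.10,0.12,102.7,0.035
5.0,F,18.20,0.13,109.4,0.035
6.0,F,20.20,0.13,115.1,0.035
8.0,F,25.80,0.14,127.8,0.035
10.0,F,31.90,0.15,138.6,0.035
12.0,F,41.50,0.15,151.2,0.035
14.0,F,49.40,0.15,160.4,0.035
16.0,F,53.90,0.14,162.5,0.035
18.0,F,56.70,0.14,163.0,0.035
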