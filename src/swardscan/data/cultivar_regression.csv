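cultivar,slope,slope_sd,y_intercept,y_intercept_sd,x_intercept,r2,p_slope
1,251687,18797,-24786555,2701665,98.48,0.9945,0.0475
2,367976,9248,-36712222,1329168,99.77,0.9994,0.016
3,268352,31270,-27599719,4494494,102.8,0.9866,0.0739
4,296257,50781,-29848658,7298879,100.8,0.9715,0.1081
5,375228,14687,-39844763,2111043,106.2,0.9985,0.0249
6,254370,8264,-25279526,1187740,99.38,0.9989,0.0207
7,213756,2424,-21271669,348411,99.51,0.9999,0.0072
8,287494,957.5,-28144506,137617,97.91,,0.0021
9,288594,2449,-26977390,351961,93.48,0.9999,0.0054
10,318106,5578,-33444196,801692,105.1,0.9997,0.0112
11,333438,16568,-34701094,2381281,104.1,0.9975,0.0316
12,212148,7899,-19647030,1135327,92.61,0.9986,0.0237
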