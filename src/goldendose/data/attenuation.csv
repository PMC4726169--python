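material,kind,energy_keV,value_cm2_per_g
gold,photoelectric,1,4652
gold,photoelectric,1.08998,3849.98
gold,photoelectric,1.18806,3186.22
gold,photoelectric,1.29497,2636.9
gold,photoelectric,1.4115,2182.29
gold,photoelectric,1.53851,1806.06
gold,photoelectric,1.67695,1494.68
gold,photoelectric,1.82785,1236.99
gold,photoelectric,1.99232,1023.73
gold,photoelectric,2.1716,847.235
gold,photoelectric,2.36701,701.168
gold,photoelectric,2.58,580.284
gold,photoelectric,2.58,1160.79
gold,photoelectric,2.80894,1089.26
gold,photoelectric,3.05819,1011.79
gold,photoelectric,3.32957,930.336
gold,photoelectric,3.62502,846.785
gold,photoelectric,3.94669,762.943
gold,photoelectric,4.29691,680.452
gold,photoelectric,4.6782,600.742
gold,photoelectric,5.09333,525.007
gold,photoelectric,5.54529,454.179
gold,photoelectric,6.03736,388.934
gold,photoelectric,6.57309,329.693
gold,photoelectric,7.15637,276.65
gold,photoelectric,7.7914,229.792
gold,photoelectric,8.48278,188.941
gold,photoelectric,9.23551,153.782
gold,photoelectric,10.055,123.899
gold,photoelectric,10.9473,98.8136
gold,photoelectric,11.9187,78.0103
gold,photoelectric,11.9187,195.008
gold,photoelectric,12.2614,180.639
gold,photoelectric,12.6139,167.329
gold,photoelectric,12.9766,155
gold,photoelectric,13.3498,143.579
gold,photoelectric,13.7336,133
gold,photoelectric,13.7336,187.554
gold,photoelectric,13.8553,183.14
gold,photoelectric,13.978,178.83
gold,photoelectric,14.1018,174.622
gold,photoelectric,14.2268,170.513
gold,photoelectric,14.3528,166.5
gold,photoelectric,14.3528,189.825
gold,photoelectric,15.6473,150.347
gold,photoelectric,17.0586,119.079
gold,photoelectric,18.5972,94.3138
gold,photoelectric,20.2745,74.6991
gold,photoelectric,22.1032,59.1638
gold,photoelectric,24.0967,46.8594
gold,photoelectric,26.2701,37.1139
gold,photoelectric,28.6395,29.3953
gold,photoelectric,31.2226,23.2819
gold,photoelectric,34.0386,18.4399
gold,photoelectric,37.1087,14.6049
gold,photoelectric,40.4556,11.5675
gold,photoelectric,44.1045,9.16177
gold,photoelectric,48.0824,7.25638
gold,photoelectric,52.4191,5.74725
gold,photoelectric,57.147,4.55198
gold,photoelectric,62.3013,3.6053
gold,photoelectric,67.9204,2.8555
gold,photoelectric,74.0464,2.26163
gold,photoelectric,80.7249,1.79128
gold,photoelectric,80.7249,7.522
gold,photoelectric,89.0127,5.72122
gold,photoelectric,98.1515,4.35154
gold,photoelectric,108.228,3.30977
gold,photoelectric,119.34,2.51741
gold,photoelectric,131.592,1.91473
gold,photoelectric,145.103,1.45634
gold,photoelectric,160,1.10769
gold,energy-absorption,1,4652.02
gold,energy-absorption,1.08998,3850
gold,energy-absorption,1.18806,3186.24
gold,energy-absorption,1.29497,2636.92
gold,energy-absorption,1.4115,2182.31
gold,energy-absorption,1.53851,1806.08
gold,energy-absorption,1.67695,1494.7
gold,energy-absorption,1.82785,1237.01
gold,energy-absorption,1.99232,1023.75
gold,energy-absorption,2.1716,847.255
gold,energy-absorption,2.36701,701.188
gold,energy-absorption,2.58,580.304
gold,energy-absorption,2.58,1160.81
gold,energy-absorption,2.80894,1089.28
gold,energy-absorption,3.05819,1011.81
gold,energy-absorption,3.32957,930.356
gold,energy-absorption,3.62502,846.805
gold,energy-absorption,3.94669,762.963
gold,energy-absorption,4.29691,680.472
gold,energy-absorption,4.6782,600.762
gold,energy-absorption,5.09333,525.027
gold,energy-absorption,5.54529,454.199
gold,energy-absorption,6.03736,388.954
gold,energy-absorption,6.57309,329.713
gold,energy-absorption,7.15637,276.67
gold,energy-absorption,7.7914,229.812
gold,energy-absorption,8.48278,188.961
gold,energy-absorption,9.23551,153.802
gold,energy-absorption,10.055,123.919
gold,energy-absorption,10.9473,98.8336
gold,energy-absorption,11.9187,78.0303
gold,energy-absorption,11.9187,157.004
gold,energy-absorption,12.2614,146.421
gold,energy-absorption,12.6139,136.52
gold,energy-absorption,12.9766,127.261
gold,energy-absorption,13.3498,118.604
gold,energy-absorption,13.7336,110.514
gold,energy-absorption,13.7336,155.836
gold,energy-absorption,13.8553,152.441
gold,energy-absorption,13.978,149.118
gold,energy-absorption,14.1018,145.864
gold,energy-absorption,14.2268,142.679
gold,energy-absorption,14.3528,139.56
gold,energy-absorption,14.3528,159.109
gold,energy-absorption,15.6473,128.037
gold,energy-absorption,17.0586,102.876
gold,energy-absorption,18.5972,82.5478
gold,energy-absorption,20.2745,66.1566
gold,energy-absorption,22.1032,52.9631
gold,energy-absorption,24.0967,42.36
gold,energy-absorption,26.2701,33.8506
gold,energy-absorption,28.6395,27.0299
gold,energy-absorption,31.2226,21.5689
gold,energy-absorption,34.0386,17.2009
gold,energy-absorption,37.1087,13.7102
gold,energy-absorption,40.4556,10.923
gold,energy-absorption,44.1045,8.69901
gold,energy-absorption,48.0824,6.92565
gold,energy-absorption,52.4191,5.51245
gold,energy-absorption,57.147,4.38687
gold,energy-absorption,62.3013,3.49081
gold,energy-absorption,67.9204,2.77779
gold,energy-absorption,74.0464,2.21065
gold,energy-absorption,80.7249,1.75971
gold,energy-absorption,80.7249,2.89042
gold,energy-absorption,89.0127,2.53265
gold,energy-absorption,98.1515,2.15834
gold,energy-absorption,108.228,1.80315
gold,energy-absorption,119.34,1.48437
gold,energy-absorption,131.592,1.20837
gold,energy-absorption,145.103,0.975313
gold,energy-absorption,160,0.782091
water,energy-absorption,1,4065
water,energy-absorption,1.5,1374
water,energy-absorption,2,615.2
water,energy-absorption,3,191.7
water,energy-absorption,4,81.91
water,energy-absorption,5,41.88
water,energy-absorption,6,24.05
water,energy-absorption,8,9.915
water,energy-absorption,10,4.944
water,energy-absorption,15,1.374
water,energy-absorption,20,0.5503
water,energy-absorption,30,0.1557
water,energy-absorption,40,0.06947
water,energy-absorption,50,0.04223
water,energy-absorption,60,0.0319
water,energy-absorption,80,0.02597
water,energy-absorption,100,0.02546
water,energy-absorption,150,0.02764
water,energy-absorption,160,0.028
water,total,1,4078
water,total,1.5,1376
water,total,2,617.1
water,total,3,192.9
water,total,4,82.78
water,total,5,42.58
water,total,6,24.64
water,total,8,10.37
water,total,10,5.329
water,total,15,1.673
water,total,20,0.8096
water,total,30,0.3756
water,total,40,0.2683
water,total,50,0.2269
water,total,60,0.2059
water,total,80,0.1837
water,total,100,0.1707
water,total,150,0.1505
water,total,160,0.148
aluminum,total,1,1185
aluminum,total,1.5,402.2
aluminum,total,1.5596,362.1
aluminum,total,1.5596,3957
aluminum,total,2,2263
aluminum,total,3,788
aluminum,total,4,360.5
aluminum,total,5,193.4
aluminum,total,6,115.3
aluminum,total,8,50.33
aluminum,total,10,26.23
aluminum,total,15,7.955
aluminum,total,20,3.441
aluminum,total,30,1.128
aluminum,total,40,0.5685
aluminum,total,50,0.3681
aluminum,total,60,0.2778
aluminum,total,80,0.2018
aluminum,total,100,0.1704
aluminum,total,150,0.1378
aluminum,total,160,0.133
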