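melatonin_uM,fc_percent,day,species,n_leaves,leaf_length_cm,internode_cm,crown_cm,height_cm
0,100,15,persian,678.00,12.675,5.390,3.450,178
0,100,30,persian,664.25,12.925,5.765,3.447,178.7
0,100,45,persian,651.50,13.075,6.022,3.435,180.1
0,100,60,persian,644.75,13.075,6.197,2.130,180.5
0,75,15,persian,168.25,3.650,1.375,1.180,110.3
0,75,30,persian,162.75,3.375,1.390,1.145,110.6
0,75,45,persian,161.25,3.325,1.390,1.127,111
0,75,60,persian,163.75,2.925,1.397,1.105,94.9
0,40,15,persian,136.25,3.400,1.197,1.172,97
0,40,30,persian,134.50,3.475,1.202,1.172,98
0,40,45,persian,133.25,3.125,1.202,1.130,98.1
0,40,60,persian,124.50,2.900,1.202,1.067,149.7
50,100,15,persian,513.50,6.125,2.892,3.095,149.7
50,100,30,persian,511.00,5.975,2.892,3.115,149.9
50,100,45,persian,503.75,5.550,2.955,3.120,150.1
50,100,60,persian,499.50,5.375,2.897,3.437,120.2
50,75,15,persian,297.25,5.325,1.825,2.137,120.6
50,75,30,persian,291.25,5.225,1.845,2.125,120.8
50,75,45,persian,287.00,4.550,1.852,2.117,120.8
50,75,60,persian,282.75,4.500,1.852,3.100,120.8
50,40,15,persian,254.50,4.325,1.592,2.110,124.9
50,40,30,persian,248.75,3.900,1.595,2.090,125.7
50,40,45,persian,245.00,3.800,1.595,2.057,126
50,40,60,persian,239.00,3.525,1.595,2.147,126.1
100,100,15,persian,774.00,12.625,8.375,3.642,174.9
100,100,30,persian,772.00,12.975,8.620,3.597,178.5
100,100,45,persian,768.75,12.875,8.720,3.607,179.3
100,100,60,persian,766.50,13.00,8.880,3.600,179.6
100,75,15,persian,622.25,9.700,7.362,3.487,175.5
100,75,30,persian,619.25,10.075,7.807,3.452,178.5
100,75,45,persian,626.25,10.175,7.895,3.432,180.1
100,75,60,persian,625.04,10.325,8.115,3.425,189.5
100,40,15,persian,540.25,8.675,5.325,3.437,165.5
100,40,30,persian,539.75,8.525,5.962,3.307,166.3
100,40,45,persian,535.75,8.475,5.980,3.310,166.6
100,40,60,persian,538.50,8.325,6.212,3.305,166.8
150,100,15,persian,511.00,7.625,3.192,3.262,156.2
150,100,30,persian,508.25,7.400,3.295,3.340,156.5
150,100,45,persian,503.75,7.200,3.360,3.232,156.8
150,100,60,persian,499.50,7.075,3.370,3.265,157
150,75,15,persian,459.00,5.225,2.650,2.447,140.2
150,75,30,persian,453.50,5.150,2.710,2.427,140.2
150,75,45,persian,449.75,4.525,2.732,2.425,140.6
150,75,60,persian,446.50,4.425,2.750,2.402,140.6
150,40,15,persian,404.25,4.400,2.120,2.280,135.2
150,40,30,persian,397.50,3.975,2.340,2.285,135.8
150,40,45,persian,388.00,3.675,2.420,2.240,136
150,40,60,persian,382.00,3.350,2.475,2.185,136.2
0,100,15,mexican,1024.50,8.150,3.240,2.577,345.5
0,100,30,mexican,1017.50,8.275,3.660,2.590,347.6
0,100,45,mexican,1014.75,8.425,3.830,2.590,348.2
0,100,60,mexican,1009.25,8.575,4.297,1.265,348.6
0,75,15,mexican,458.25,2.375,1.062,1.057,191.8
0,75,30,mexican,455.50,2.125,1.072,1.032,192.1
0,75,45,mexican,443.75,2.050,1.072,1.017,192.4
0,75,60,mexican,438.50,1.825,1.072,1.035,192.5
0,40,15,mexican,370.00,1.650,0.850,1.080,179.1
0,40,30,mexican,362.50,1.300,0.852,1.037,178.7
0,40,45,mexican,351.50,1.150,0.855,1.030,177
0,40,60,mexican,349.25,1.125,0.855,1.025,177
50,100,15,mexican,826.00,3.750,1.992,1.822,330.1
50,100,30,mexican,820.50,3.500,2.025,1.880,330.4
50,100,45,mexican,814.50,3.425,2.042,1.880,330.5
50,100,60,mexican,811.75,3.150,2.052,1.880,330.5
50,75,15,mexican,485.00,2.775,1.347,1.233,220.6
50,75,30,mexican,476.25,2.600,1.375,1.217,220.8
50,75,45,mexican,470.00,2.550,1.387,1.212,221.3
50,75,60,mexican,465.25,2.375,1.450,1.135,221.4
50,40,15,mexican,482.50,2.700,1.192,1.235,215.6
50,40,30,mexican,461.50,2.225,1.197,1.217,216.2
50,40,45,mexican,453.00,2.075,1.200,1.225,216.5
50,40,60,mexican,445.50,1.550,1.202,1.250,216.7
100,100,15,mexican,1063.25,8.375,6.135,2.855,344.5
100,100,30,mexican,105.50,8.750,6.410,2.845,347.2
100,100,45,mexican,1059.25,8.900,6.680,2.810,347.7
100,100,60,mexican,1061.00,9.025,6.785,2.795,348.4
100,75,15,mexican,1022.00,5.700,5.172,2.640,345.6
100,75,30,mexican,1023.50,5.825,5.580,2.650,347.4
100,75,45,mexican,1019.25,5.975,5.755,2.630,348.1
100,75,60,mexican,1013.75,6.100,5.955,2.602,348.7
100,40,15,mexican,877.50,4.500,3.137,2.385,339
100,40,30,mexican,875.25,4.425,3.650,2.360,340.6
100,40,45,mexican,874.25,4.325,3.815,2.275,341.1
100,40,60,mexican,827.50,4.175,4.377,2.260,341.8
150,100,15,mexican,827.50,4.300,2.390,2.120,332.9
150,100,30,mexican,823.00,4.100,2.375,2.110,333.3
150,100,45,mexican,820.00,3.975,2.420,2.072,333.4
150,100,60,mexican,815.00,3.825,2.422,2.070,333.4
150,75,15,mexican,770.50,3.025,1.692,1.655,320.6
150,75,30,mexican,763.50,2.625,1.715,1.635,321.2
150,75,45,mexican,745.00,2.550,1.732,1.617,321.2
150,75,60,mexican,757.50,2.100,1.755,1.612,321.2
150,40,15,mexican,626.75,2.400,1.132,1.440,316
150,40,30,mexican,617.25,1.925,1.285,1.405,316.9
150,40,45,mexican,602.50,1.725,1.390,1.395,317.2
150,40,60,mexican,593.00,1.625,1.447,1.395,317.5
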