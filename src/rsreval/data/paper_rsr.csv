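region,year,dimension,rsr,rank
Beijing,2009,needs,0.147,29
Tianjin,2009,needs,0.175,28
Hebei,2009,needs,0.290,13
Shanxi,2009,needs,0.240,21
Inner Mongolia,2009,needs,0.253,16
Liaoning,2009,needs,0.214,25
Jilin,2009,needs,0.245,19
Heilongjiang,2009,needs,0.305,10
Shanghai,2009,needs,0.355,8
Jiangsu,2009,needs,0.229,22
Zhejiang,2009,needs,0.146,30
Anhui,2009,needs,0.304,11
Fujian,2009,needs,0.144,31
Jiangxi,2009,needs,0.254,15
Shandong,2009,needs,0.229,23
Henan,2009,needs,0.245,18
Hubei,2009,needs,0.262,14
Hunan,2009,needs,0.208,26
Guangdong,2009,needs,0.253,17
Guangxi,2009,needs,0.218,24
Hainan,2009,needs,0.320,9
Chongqing,2009,needs,0.425,4
Sichuan,2009,needs,0.358,7
Guizhou,2009,needs,0.384,5
Yunnan,2009,needs,0.375,6
Xizang,2009,needs,0.863,1
Shaanxi,2009,needs,0.201,27
Gansu,2009,needs,0.299,12
Qinghai,2009,needs,0.640,2
Ningxia,2009,needs,0.241,20
Xinjiang,2009,needs,0.473,3
Beijing,2009,resources,0.557,1
Tianjin,2009,resources,0.348,14
Hebei,2009,resources,0.360,13
Shanxi,2009,resources,0.496,5
Inner Mongolia,2009,resources,0.503,4
Liaoning,2009,resources,0.227,26
Jilin,2009,resources,0.441,10
Heilongjiang,2009,resources,0.312,19
Shanghai,2009,resources,0.252,24
Jiangsu,2009,resources,0.099,31
Zhejiang,2009,resources,0.490,6
Anhui,2009,resources,0.117,30
Fujian,2009,resources,0.253,23
Jiangxi,2009,resources,0.327,16
Shandong,2009,resources,0.301,21
Henan,2009,resources,0.304,20
Hubei,2009,resources,0.323,17
Hunan,2009,resources,0.313,18
Guangdong,2009,resources,0.447,8
Guangxi,2009,resources,0.442,9
Hainan,2009,resources,0.396,12
Chongqing,2009,resources,0.160,28
Sichuan,2009,resources,0.199,27
Guizhou,2009,resources,0.154,29
Yunnan,2009,resources,0.241,25
Xizang,2009,resources,0.474,7
Shaanxi,2009,resources,0.415,11
Gansu,2009,resources,0.331,15
Qinghai,2009,resources,0.300,22
Ningxia,2009,resources,0.538,2
Xinjiang,2009,resources,0.512,3
Beijing,2009,utilization,0.814,1
Tianjin,2009,utilization,0.736,12
Hebei,2009,utilization,0.705,15
Shanxi,2009,utilization,0.578,26
Inner Mongolia,2009,utilization,0.743,11
Liaoning,2009,utilization,0.796,4
Jilin,2009,utilization,0.591,25
Heilongjiang,2009,utilization,0.691,17
Shanghai,2009,utilization,0.616,23
Jiangsu,2009,utilization,0.785,6
Zhejiang,2009,utilization,0.804,2
Anhui,2009,utilization,0.290,30
Fujian,2009,utilization,0.727,13
Jiangxi,2009,utilization,0.658,19
Shandong,2009,utilization,0.803,3
Henan,2009,utilization,0.780,8
Hubei,2009,utilization,0.751,10
Hunan,2009,utilization,0.705,16
Guangdong,2009,utilization,0.722,14
Guangxi,2009,utilization,0.755,9
Hainan,2009,utilization,0.506,29
Chongqing,2009,utilization,0.591,24
Sichuan,2009,utilization,0.630,21
Guizhou,2009,utilization,0.578,27
Yunnan,2009,utilization,0.683,18
Xizang,2009,utilization,0.032,31
Shaanxi,2009,utilization,0.782,7
Gansu,2009,utilization,0.656,20
Qinghai,2009,utilization,0.539,28
Ningxia,2009,utilization,0.791,5
Xinjiang,2009,utilization,0.628,22
Beijing,2019,needs,0.032,31
Tianjin,2019,needs,0.519,2
Hebei,2019,needs,0.205,25
Shanxi,2019,needs,0.272,15
Inner Mongolia,2019,needs,0.209,24
Liaoning,2019,needs,0.321,7
Jilin,2019,needs,0.303,10
Heilongjiang,2019,needs,0.342,5
Shanghai,2019,needs,0.033,30
Jiangsu,2019,needs,0.248,20
Zhejiang,2019,needs,0.276,14
Anhui,2019,needs,0.250,19
Fujian,2019,needs,0.268,16
Jiangxi,2019,needs,0.255,17
Shandong,2019,needs,0.240,22
Henan,2019,needs,0.276,13
Hubei,2019,needs,0.252,18
Hunan,2019,needs,0.201,26
Guangdong,2019,needs,0.170,28
Guangxi,2019,needs,0.218,23
Hainan,2019,needs,0.129,29
Chongqing,2019,needs,0.183,27
Sichuan,2019,needs,0.310,9
Guizhou,2019,needs,0.290,11
Yunnan,2019,needs,0.325,6
Xizang,2019,needs,0.785,1
Shaanxi,2019,needs,0.244,21
Gansu,2019,needs,0.284,12
Qinghai,2019,needs,0.439,3
Ningxia,2019,needs,0.386,4
Xinjiang,2019,needs,0.313,8
Beijing,2019,resources,0.382,16
Tianjin,2019,resources,0.069,31
Hebei,2019,resources,0.377,18
Shanxi,2019,resources,0.331,23
Inner Mongolia,2019,resources,0.492,7
Liaoning,2019,resources,0.156,29
Jilin,2019,resources,0.231,25
Heilongjiang,2019,resources,0.199,28
Shanghai,2019,resources,0.091,30
Jiangsu,2019,resources,0.222,26
Zhejiang,2019,resources,0.493,6
Anhui,2019,resources,0.211,27
Fujian,2019,resources,0.337,22
Jiangxi,2019,resources,0.370,19
Shandong,2019,resources,0.412,14
Henan,2019,resources,0.380,17
Hubei,2019,resources,0.424,13
Hunan,2019,resources,0.492,8
Guangdong,2019,resources,0.444,12
Guangxi,2019,resources,0.526,5
Hainan,2019,resources,0.387,15
Chongqing,2019,resources,0.261,24
Sichuan,2019,resources,0.349,21
Guizhou,2019,resources,0.569,1
Yunnan,2019,resources,0.466,9
Xizang,2019,resources,0.531,4
Shaanxi,2019,resources,0.462,10
Gansu,2019,resources,0.451,11
Qinghai,2019,resources,0.532,3
Ningxia,2019,resources,0.547,2
Xinjiang,2019,resources,0.364,20
Beijing,2019,utilization,0.866,19
Tianjin,2019,utilization,0.973,2
Hebei,2019,utilization,0.856,22
Shanxi,2019,utilization,0.793,27
Inner Mongolia,2019,utilization,0.930,7
Liaoning,2019,utilization,0.904,14
Jilin,2019,utilization,0.937,6
Heilongjiang,2019,utilization,0.913,12
Shanghai,2019,utilization,0.962,4
Jiangsu,2019,utilization,0.846,24
Zhejiang,2019,utilization,0.984,1
Anhui,2019,utilization,0.857,21
Fujian,2019,utilization,0.899,16
Jiangxi,2019,utilization,0.915,10
Shandong,2019,utilization,0.890,17
Henan,2019,utilization,0.746,29
Hubei,2019,utilization,0.916,9
Hunan,2019,utilization,0.939,5
Guangdong,2019,utilization,0.907,13
Guangxi,2019,utilization,0.970,3
Hainan,2019,utilization,0.852,23
Chongqing,2019,utilization,0.903,15
Sichuan,2019,utilization,0.913,11
Guizhou,2019,utilization,0.865,20
Yunnan,2019,utilization,0.753,28
Xizang,2019,utilization,0.032,31
Shaanxi,2019,utilization,0.921,8
Gansu,2019,utilization,0.887,18
Qinghai,2019,utilization,0.808,26
Ningxia,2019,utilization,0.723,30
Xinjiang,2019,utilization,0.821,25
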