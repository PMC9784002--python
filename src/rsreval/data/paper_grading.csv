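region,year,dimension,fitted_rsr,grade
Fujian,2009,needs,0.046,Low
Zhejiang,2009,needs,0.089,Low
Beijing,2009,needs,0.118,Low
Tianjin,2009,needs,0.140,Low
Shaanxi,2009,needs,0.159,Medium
Hunan,2009,needs,0.175,Medium
Liaoning,2009,needs,0.190,Medium
Guangxi,2009,needs,0.204,Medium
Shandong,2009,needs,0.217,Medium
Jiangsu,2009,needs,0.229,Medium
Shanxi,2009,needs,0.240,Medium
Ningxia,2009,needs,0.252,Medium
Jilin,2009,needs,0.263,Medium
Henan,2009,needs,0.274,Medium
Guangdong,2009,needs,0.284,Medium
Inner Mongolia,2009,needs,0.295,Medium
Jiangxi,2009,needs,0.306,Medium
Hubei,2009,needs,0.316,Medium
Hebei,2009,needs,0.327,Medium
Gansu,2009,needs,0.339,Medium
Anhui,2009,needs,0.350,Medium
Heilongjiang,2009,needs,0.362,Medium
Hainan,2009,needs,0.375,Medium
Shanghai,2009,needs,0.389,Medium
Sichuan,2009,needs,0.404,Medium
Yunnan,2009,needs,0.420,Medium
Guizhou,2009,needs,0.439,High
Chongqing,2009,needs,0.461,High
Xinjiang,2009,needs,0.490,High
Qinghai,2009,needs,0.534,High
Xizang,2009,needs,0.607,High
Jiangsu,2009,resources,0.102,Low
Anhui,2009,resources,0.143,Low
Guizhou,2009,resources,0.170,Low
Chongqing,2009,resources,0.192,Low
Sichuan,2009,resources,0.209,Medium
Liaoning,2009,resources,0.225,Medium
Yunnan,2009,resources,0.239,Medium
Shanghai,2009,resources,0.252,Medium
Fujian,2009,resources,0.264,Medium
Qinghai,2009,resources,0.276,Medium
Shandong,2009,resources,0.287,Medium
Henan,2009,resources,0.297,Medium
Heilongjiang,2009,resources,0.308,Medium
Hunan,2009,resources,0.318,Medium
Hubei,2009,resources,0.328,Medium
Jiangxi,2009,resources,0.338,Medium
Gansu,2009,resources,0.349,Medium
Tianjin,2009,resources,0.359,Medium
Hebei,2009,resources,0.369,Medium
Hainan,2009,resources,0.380,Medium
Shaanxi,2009,resources,0.391,Medium
Jilin,2009,resources,0.402,Medium
Guangxi,2009,resources,0.415,Medium
Guangdong,2009,resources,0.428,Medium
Xizang,2009,resources,0.442,Medium
Zhejiang,2009,resources,0.457,Medium
Shanxi,2009,resources,0.475,High
Inner Mongolia,2009,resources,0.496,High
Xinjiang,2009,resources,0.523,High
Ningxia,2009,resources,0.565,High
Beijing,2009,resources,0.635,High
Xizang,2009,utilization,0.399,Low
Anhui,2009,utilization,0.444,Low
Hainan,2009,utilization,0.473,Low
Qinghai,2009,utilization,0.496,Low
Guizhou,2009,utilization,0.515,Medium
Shanxi,2009,utilization,0.532,Medium
Jilin,2009,utilization,0.548,Medium
Chongqing,2009,utilization,0.562,Medium
Shanghai,2009,utilization,0.575,Medium
Xinjiang,2009,utilization,0.587,Medium
Sichuan,2009,utilization,0.599,Medium
Gansu,2009,utilization,0.611,Medium
Jiangxi,2009,utilization,0.622,Medium
Yunnan,2009,utilization,0.633,Medium
Heilongjiang,2009,utilization,0.644,Medium
Hunan,2009,utilization,0.655,Medium
Hebei,2009,utilization,0.666,Medium
Guangdong,2009,utilization,0.677,Medium
Fujian,2009,utilization,0.689,Medium
Tianjin,2009,utilization,0.700,Medium
Inner Mongolia,2009,utilization,0.712,Medium
Hubei,2009,utilization,0.725,Medium
Guangxi,2009,utilization,0.738,Medium
Henan,2009,utilization,0.752,Medium
Shaanxi,2009,utilization,0.767,Medium
Jiangsu,2009,utilization,0.784,Medium
Ningxia,2009,utilization,0.803,High
Liaoning,2009,utilization,0.826,High
Shandong,2009,utilization,0.856,High
Zhejiang,2009,utilization,0.901,High
Beijing,2009,utilization,0.976,High
Beijing,2019,needs,0.035,Low
Shanghai,2019,needs,0.077,Low
Hainan,2019,needs,0.104,Low
Guangdong,2019,needs,0.125,Low
Chongqing,2019,needs,0.143,Medium
Hunan,2019,needs,0.159,Medium
Hebei,2019,needs,0.173,Medium
Inner Mongolia,2019,needs,0.186,Medium
Guangxi,2019,needs,0.198,Medium
Shandong,2019,needs,0.209,Medium
Shaanxi,2019,needs,0.220,Medium
Jiangsu,2019,needs,0.231,Medium
Anhui,2019,needs,0.241,Medium
Hubei,2019,needs,0.252,Medium
Jiangxi,2019,needs,0.262,Medium
Fujian,2019,needs,0.272,Medium
Shanxi,2019,needs,0.282,Medium
Zhejiang,2019,needs,0.292,Medium
Henan,2019,needs,0.303,Medium
Gansu,2019,needs,0.314,Medium
Guizhou,2019,needs,0.325,Medium
Jilin,2019,needs,0.336,Medium
Sichuan,2019,needs,0.348,Medium
Xinjiang,2019,needs,0.361,Medium
Liaoning,2019,needs,0.375,Medium
Yunnan,2019,needs,0.391,Medium
Heilongjiang,2019,needs,0.409,High
Ningxia,2019,needs,0.430,High
Qinghai,2019,needs,0.457,High
Tianjin,2019,needs,0.499,High
Xizang,2019,needs,0.569,High
Tianjin,2019,resources,0.122,Low
Shanghai,2019,resources,0.165,Low
Liaoning,2019,resources,0.193,Low
Heilongjiang,2019,resources,0.215,Low
Anhui,2019,resources,0.234,Medium
Jiangsu,2019,resources,0.250,Medium
Jilin,2019,resources,0.265,Medium
Chongqing,2019,resources,0.278,Medium
Shanxi,2019,resources,0.291,Medium
Fujian,2019,resources,0.303,Medium
Sichuan,2019,resources,0.314,Medium
Xinjiang,2019,resources,0.325,Medium
Jiangxi,2019,resources,0.336,Medium
Hebei,2019,resources,0.347,Medium
Henan,2019,resources,0.357,Medium
Beijing,2019,resources,0.368,Medium
Hainan,2019,resources,0.379,Medium
Shandong,2019,resources,0.389,Medium
Hubei,2019,resources,0.400,Medium
Guangdong,2019,resources,0.411,Medium
Gansu,2019,resources,0.423,Medium
Shaanxi,2019,resources,0.435,Medium
Yunnan,2019,resources,0.447,Medium
Hunan,2019,resources,0.461,Medium
Inner Mongolia,2019,resources,0.475,Medium
Zhejiang,2019,resources,0.492,Medium
Guangxi,2019,resources,0.510,High
Xizang,2019,resources,0.532,High
Qinghai,2019,resources,0.561,High
Ningxia,2019,resources,0.604,High
Guizhou,2019,resources,0.676,High
Xizang,2019,utilization,0.637,Low
Ningxia,2019,utilization,0.674,Low
Henan,2019,utilization,0.699,Low
Yunnan,2019,utilization,0.718,Low
Shanxi,2019,utilization,0.734,Medium
Qinghai,2019,utilization,0.748,Medium
Xinjiang,2019,utilization,0.760,Medium
Jiangsu,2019,utilization,0.772,Medium
Hainan,2019,utilization,0.783,Medium
Hebei,2019,utilization,0.793,Medium
Anhui,2019,utilization,0.803,Medium
Guizhou,2019,utilization,0.813,Medium
Beijing,2019,utilization,0.822,Medium
Gansu,2019,utilization,0.832,Medium
Shandong,2019,utilization,0.841,Medium
Fujian,2019,utilization,0.850,Medium
Chongqing,2019,utilization,0.859,Medium
Liaoning,2019,utilization,0.868,Medium
Guangdong,2019,utilization,0.878,Medium
Heilongjiang,2019,utilization,0.888,Medium
Sichuan,2019,utilization,0.897,Medium
Jiangxi,2019,utilization,0.908,Medium
Hubei,2019,utilization,0.919,Medium
Shaanxi,2019,utilization,0.930,Medium
Inner Mongolia,2019,utilization,0.943,Medium
Jilin,2019,utilization,0.957,Medium
Hunan,2019,utilization,0.973,High
Shanghai,2019,utilization,0.992,High
Guangxi,2019,utilization,1.017,High
Tianjin,2019,utilization,1.054,High
Zhejiang,2019,utilization,1.117,High
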