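region,year,dimension,p,probit
Beijing,2009,needs,9.7,3.700
Tianjin,2009,needs,12.9,3.869
Hebei,2009,needs,61.3,5.287
Shanxi,2009,needs,35.5,4.628
Inner Mongolia,2009,needs,48.4,4.960
Liaoning,2009,needs,22.6,4.247
Jilin,2009,needs,41.9,4.796
Heilongjiang,2009,needs,71.0,5.552
Shanghai,2009,needs,77.4,5.753
Jiangsu,2009,needs,29.0,4.448
Zhejiang,2009,needs,6.5,3.482
Anhui,2009,needs,67.7,5.460
Fujian,2009,needs,3.2,3.151
Jiangxi,2009,needs,54.8,5.122
Shandong,2009,needs,32.3,4.540
Henan,2009,needs,45.2,4.878
Hubei,2009,needs,58.1,5.204
Hunan,2009,needs,19.4,4.135
Guangdong,2009,needs,51.6,5.040
Guangxi,2009,needs,25.8,4.351
Hainan,2009,needs,74.2,5.649
Chongqing,2009,needs,90.3,6.300
Sichuan,2009,needs,80.6,5.865
Guizhou,2009,needs,87.1,6.131
Yunnan,2009,needs,83.9,5.989
Xizang,2009,needs,99.2,7.406
Shaanxi,2009,needs,16.1,4.011
Gansu,2009,needs,64.5,5.372
Qinghai,2009,needs,96.8,6.849
Ningxia,2009,needs,38.7,4.713
Xinjiang,2009,needs,93.5,6.518
Beijing,2009,resources,99.2,7.406
Tianjin,2009,resources,58.1,5.204
Hebei,2009,resources,61.3,5.287
Shanxi,2009,resources,87.1,6.131
Inner Mongolia,2009,resources,90.3,6.300
Liaoning,2009,resources,19.4,4.135
Jilin,2009,resources,71.0,5.552
Heilongjiang,2009,resources,41.9,4.796
Shanghai,2009,resources,25.8,4.351
Jiangsu,2009,resources,3.2,3.151
Zhejiang,2009,resources,83.9,5.989
Anhui,2009,resources,6.5,3.482
Fujian,2009,resources,29.0,4.448
Jiangxi,2009,resources,51.6,5.040
Shandong,2009,resources,35.5,4.628
Henan,2009,resources,38.7,4.713
Hubei,2009,resources,48.4,4.960
Hunan,2009,resources,45.2,4.878
Guangdong,2009,resources,77.4,5.753
Guangxi,2009,resources,74.2,5.649
Hainan,2009,resources,64.5,5.372
Chongqing,2009,resources,12.9,3.869
Sichuan,2009,resources,16.1,4.011
Guizhou,2009,resources,9.7,3.700
Yunnan,2009,resources,22.6,4.247
Xizang,2009,resources,80.6,5.865
Shaanxi,2009,resources,67.7,5.460
Gansu,2009,resources,54.8,5.122
Qinghai,2009,resources,32.3,4.540
Ningxia,2009,resources,96.8,6.849
Xinjiang,2009,resources,93.5,6.518
Beijing,2009,utilization,99.2,7.406
Tianjin,2009,utilization,64.5,5.372
Hebei,2009,utilization,54.8,5.122
Shanxi,2009,utilization,19.4,4.135
Inner Mongolia,2009,utilization,67.7,5.460
Liaoning,2009,utilization,90.3,6.300
Jilin,2009,utilization,22.6,4.247
Heilongjiang,2009,utilization,48.4,4.960
Shanghai,2009,utilization,29.0,4.448
Jiangsu,2009,utilization,83.9,5.989
Zhejiang,2009,utilization,96.8,6.849
Anhui,2009,utilization,6.5,3.482
Fujian,2009,utilization,61.3,5.287
Jiangxi,2009,utilization,41.9,4.796
Shandong,2009,utilization,93.5,6.518
Henan,2009,utilization,77.4,5.753
Hubei,2009,utilization,71.0,5.552
Hunan,2009,utilization,51.6,5.040
Guangdong,2009,utilization,58.1,5.204
Guangxi,2009,utilization,74.2,5.649
Hainan,2009,utilization,9.7,3.700
Chongqing,2009,utilization,25.8,4.351
Sichuan,2009,utilization,35.5,4.628
Guizhou,2009,utilization,16.1,4.011
Yunnan,2009,utilization,45.2,4.878
Xizang,2009,utilization,3.2,3.151
Shaanxi,2009,utilization,80.6,5.865
Gansu,2009,utilization,38.7,4.713
Qinghai,2009,utilization,12.9,3.869
Ningxia,2009,utilization,87.1,6.131
Xinjiang,2009,utilization,32.3,4.540
Beijing,2019,needs,3.2,3.151
Tianjin,2019,needs,96.8,6.849
Hebei,2019,needs,22.6,4.247
Shanxi,2019,needs,54.8,5.122
Inner Mongolia,2019,needs,25.8,4.351
Liaoning,2019,needs,80.6,5.865
Jilin,2019,needs,71.0,5.552
Heilongjiang,2019,needs,87.1,6.131
Shanghai,2019,needs,6.5,3.482
Jiangsu,2019,needs,38.7,4.713
Zhejiang,2019,needs,58.1,5.204
Anhui,2019,needs,41.9,4.796
Fujian,2019,needs,51.6,5.040
Jiangxi,2019,needs,48.4,4.960
Shandong,2019,needs,32.3,4.540
Henan,2019,needs,61.3,5.287
Hubei,2019,needs,45.2,4.878
Hunan,2019,needs,19.4,4.135
Guangdong,2019,needs,12.9,3.869
Guangxi,2019,needs,29.0,4.448
Hainan,2019,needs,9.7,3.700
Chongqing,2019,needs,16.1,4.011
Sichuan,2019,needs,74.2,5.649
Guizhou,2019,needs,67.7,5.460
Yunnan,2019,needs,83.9,5.989
Xizang,2019,needs,99.2,7.406
Shaanxi,2019,needs,35.5,4.628
Gansu,2019,needs,64.5,5.372
Qinghai,2019,needs,93.5,6.518
Ningxia,2019,needs,90.3,6.300
Xinjiang,2019,needs,77.4,5.753
Beijing,2019,resources,51.6,5.040
Tianjin,2019,resources,3.2,3.151
Hebei,2019,resources,45.2,4.878
Shanxi,2019,resources,29.0,4.448
Inner Mongolia,2019,resources,77.4,5.753
Liaoning,2019,resources,9.7,3.700
Jilin,2019,resources,22.6,4.247
Heilongjiang,2019,resources,12.9,3.869
Shanghai,2019,resources,6.5,3.482
Jiangsu,2019,resources,19.4,4.135
Zhejiang,2019,resources,83.9,5.989
Anhui,2019,resources,16.1,4.011
Fujian,2019,resources,32.3,4.540
Jiangxi,2019,resources,41.9,4.796
Shandong,2019,resources,58.1,5.204
Henan,2019,resources,48.4,4.960
Hubei,2019,resources,61.3,5.287
Hunan,2019,resources,80.6,5.865
Guangdong,2019,resources,64.5,5.372
Guangxi,2019,resources,87.1,6.131
Hainan,2019,resources,54.8,5.122
Chongqing,2019,resources,25.8,4.351
Sichuan,2019,resources,35.5,4.628
Guizhou,2019,resources,99.2,7.406
Yunnan,2019,resources,74.2,5.649
Xizang,2019,resources,90.3,6.300
Shaanxi,2019,resources,71.0,5.552
Gansu,2019,resources,67.7,5.460
Qinghai,2019,resources,93.5,6.518
Ningxia,2019,resources,96.8,6.849
Xinjiang,2019,resources,38.7,4.713
Beijing,2019,utilization,41.9,4.796
Tianjin,2019,utilization,96.8,6.849
Hebei,2019,utilization,32.3,4.540
Shanxi,2019,utilization,16.1,4.011
Inner Mongolia,2019,utilization,80.6,5.865
Liaoning,2019,utilization,58.1,5.204
Jilin,2019,utilization,83.9,5.989
Heilongjiang,2019,utilization,64.5,5.372
Shanghai,2019,utilization,90.3,6.300
Jiangsu,2019,utilization,25.8,4.351
Zhejiang,2019,utilization,99.2,7.406
Anhui,2019,utilization,35.5,4.628
Fujian,2019,utilization,51.6,5.040
Jiangxi,2019,utilization,71.0,5.552
Shandong,2019,utilization,48.4,4.960
Henan,2019,utilization,9.7,3.700
Hubei,2019,utilization,74.2,5.649
Hunan,2019,utilization,87.1,6.131
Guangdong,2019,utilization,61.3,5.287
Guangxi,2019,utilization,93.5,6.518
Hainan,2019,utilization,29.0,4.448
Chongqing,2019,utilization,54.8,5.122
Sichuan,2019,utilization,67.7,5.460
Guizhou,2019,utilization,38.7,4.713
Yunnan,2019,utilization,12.9,3.869
Xizang,2019,utilization,3.2,3.151
Shaanxi,2019,utilization,77.4,5.753
Gansu,2019,utilization,45.2,4.878
Qinghai,2019,utilization,19.4,4.135
Ningxia,2019,utilization,6.5,3.482
Xinjiang,2019,utilization,22.6,4.247
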