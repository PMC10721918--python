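province,region
Beijing,East
Tianjin,East
Hebei,East
Liaoning,East
Shanghai,East
Jiangsu,East
Zhejiang,East
Fujian,East
Shandong,East
Guangdong,East
Hainan,East
Shanxi,Central
Jilin,Central
Heilongjiang,Central
Anhui,Central
Jiangxi,Central
Henan,Central
Hubei,Central
Hunan,Central
Inner Mongolia,West
Guangxi,West
Chongqing,West
Sichuan,West
Guizhou,West
Yunnan,West
Tibet,West
Shaanxi,West
Gansu,West
Qinghai,West
Ningxia,West
Xinjiang,West
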