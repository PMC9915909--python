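region_id,2010,2015,2020
Xi'an City,75.86,76.27,80.86
Baoji City,72.12,75.00,77.88
Xianyang City,72.00,74.50,77.00
Lanzhou City,72.54,73.50,74.50
Jiayuguan City,77.79,77.99,78.19
Baiyin City,72.84,74.00,75.16
Wuwei City,71.34,73.50,75.66
Zhangye City,70.41,72.30,74.20
Pingliang City,72.23,73.25,74.00
Jiuquan City,72.81,74.80,75.60
Haibei Tibetan Autonomous Prefecture,70.41,71.33,72.24
Urumqi City,73.70,75.80,76.40
Turpan City,71.40,73.60,74.35
Hami City,74.00,75.00,76.00
Changji Hui Autonomous Prefecture,73.25,75.49,76.16
Guyuan City,70.45,71.85,76.80
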