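# SYNTHETIC stand-in atmospheric CO2 d13C curve (not a published compilation)
year_ce,d13c_atm_permil
1800,-6.400
1805,-6.400
1810,-6.400
1815,-6.400
1820,-6.400
1825,-6.400
1830,-6.400
1835,-6.400
1840,-6.400
1845,-6.400
1850,-6.400
1855,-6.401
1860,-6.404
1865,-6.411
1870,-6.420
1875,-6.433
1880,-6.450
1885,-6.470
1890,-6.494
1895,-6.521
1900,-6.553
1905,-6.589
1910,-6.628
1915,-6.672
1920,-6.721
1925,-6.773
1930,-6.830
1935,-6.891
1940,-6.957
1945,-7.028
1950,-7.103
1955,-7.182
1960,-7.267
1965,-7.356
1970,-7.449
1975,-7.548
1980,-7.651
1985,-7.760
1990,-7.873
1995,-7.991
2000,-8.115
2005,-8.243
2010,-8.376
2015,-8.514
2020,-8.658
2025,-8.807
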