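{
  "CARS": {
    "none": [1033.7, 1043.2, 1062.1, 1081.1, 1128.4, 1630.4, 1829.2, 1848.2, 1857.7, 2227.0, 2293.3, 2312.2, 2388.0, 2482.7],
    "snv + 1st derivative": [1289.4, 1403.1, 1450.4, 1469.4, 1554.6, 1649.3, 1725.1, 1753.5, 1762.9, 1819.8, 1848.2, 1867.1, 1876.6, 1895.5, 1914.5, 1971.3, 2047.1, 2075.5, 2085.0, 2132.3, 2141.8, 2151.2, 2160.7, 2236.5, 2274.4, 2283.8, 2312.2, 2369.1, 2378.5, 2435.4, 2482.7],
    "1st derivative": [1166.3, 1450.4, 1554.6, 1649.3, 1687.2, 1725.1, 1753.5, 1762.9, 1819.8, 1848.2, 1867.1, 1876.6, 1895.5, 1914.5, 1971.3, 2047.1, 2075.5, 2085.0, 2103.9, 2141.8, 2151.2, 2179.7, 2227.0, 2236.5, 2274.4, 2283.8, 2312.2, 2331.2, 2369.1, 2378.5, 2435.4],
    "osc + 1st derivative": [1166.3, 1469.4, 1554.6, 1649.3, 1725.1, 1753.5, 1762.9, 1819.8, 1848.2, 1867.1, 1876.6, 1895.5, 1971.3, 2047.1, 2075.5, 2085.0, 2141.8, 2151.2, 2179.7, 2227.0, 2236.5, 2274.4, 2283.8, 2369.1, 2378.5, 2435.4]
  },
  "IRIV": {
    "none": [1431.5, 1488.3, 1781.9, 1791.4, 1810.3, 1829.2, 2227.0, 2274.4],
    "snv + 1st derivative": [1289.4, 1469.4, 1478.8, 1630.4, 1649.3, 1810.3, 1819.8, 1971.3, 2141.8, 2151.2, 2312.2, 2369.1, 2378.5, 2435.4],
    "1st derivative": [1242.1, 1403.1, 1431.5, 1469.4, 1478.8, 1583.0, 1630.4, 1649.3, 1810.3, 1819.8, 1971.3, 2141.8, 2189.1, 2312.2, 2378.5, 2435.4],
    "|1st der| + snv": [1033.7, 1166.3, 1223.1, 1242.1, 1289.4, 1374.7, 1412.5, 1450.4, 1649.3, 1791.4, 1933.4, 1952.4, 2047.1, 2085.0, 2122.8, 2141.8, 2160.7, 2198.6, 2293.3, 2350.1, 2378.5, 2388.0]
  }
}
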