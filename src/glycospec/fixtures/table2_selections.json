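{
  "CARS": {
    "osc + 1st derivative": [1166.3, 1469.4, 1478.8, 1554.6, 1649.3, 1725.1, 1753.5, 1762.9, 1791.4, 1819.8, 1848.2, 1867.1, 1876.6, 1895.5, 1914.5, 1933.4, 1971.3, 2047.1, 2075.5, 2085.0, 2141.8, 2151.2, 2179.7, 2227.0, 2236.5, 2274.4, 2283.8, 2302.8, 2312.2, 2369.1, 2378.5, 2435.4]
  },
  "IRIV": {
    "1st derivative": [1242.1, 1403.1, 1431.5, 1469.4, 1478.8, 1583.0, 1630.4, 1649.3, 1810.3, 1819.8, 1895.5, 1933.4, 1971.3, 2009.2, 2122.8, 2141.8, 2189.1, 2255.4, 2293.3, 2312.2, 2378.5, 2416.4, 2435.4]
  }
}
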