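{
  "version": "2021-CODATA/NIST",
  "comment": "Monoisotopic masses (Da) and natural abundances (fraction) for the supported element set. electron_mass from CODATA 2018.",
  "electron_mass": 5.48579909065e-4,
  "elements": {
    "C":  [[12.0, 0.9893], [13.00335483507, 0.0107]],
    "H":  [[1.00782503207, 0.999885], [2.01410177812, 0.000115]],
    "N":  [[14.0030740048, 0.99636], [15.0001088989, 0.00364]],
    "O":  [[15.9949146196, 0.99757], [16.9991317565, 0.00038], [17.9991596129, 0.00205]],
    "S":  [[31.9720711744, 0.9499], [32.9714589098, 0.0075], [33.967867004, 0.0425], [35.96708071, 0.0001]],
    "Cl": [[34.968852682, 0.7576], [36.965902602, 0.2424]],
    "Br": [[78.9183376, 0.5069], [80.9162906, 0.4931]]
  }
}
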