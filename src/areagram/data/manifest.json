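{
 "bpa_provinces_39chars.csv": {
  "sha256": "fe5882948d2d1a3ff8d3f7c36c155db0f477b41d6b6ce45dbd387134a4052c4d",
  "note": "Published BPA coding: 20 species + 19 hypothetical-ancestor characters over the same provinces."
 },
 "provinces_23species.csv": {
  "sha256": "0200863f517271d41e5a55e129849f6a8a06761c5fa3a029948b480e0506582f",
  "note": "Published incidence matrix: 23 Tropidurus species x 20 South American biogeographic provinces, plus outgroup row."
 },
 "quadrats_23species.csv": {
  "sha256": "ddca866db619c80f82886a684302cb34b582454a6b743222abcd2223cfbc6e1c",
  "note": "Published incidence matrix: 23 Tropidurus species x 50 occupied 5-degree quadrats, plus all-zero outgroup row."
 },
 "taxon_cladogram_bpa.nwk": {
  "sha256": "7e526a4c01e89acbd904909c010646351789e4d205c1b9f87a1d1dc798f2ec67",
  "note": "Species cladogram consistent with (derived from and validated against) the ancestor columns of the BPA coding."
 }
}
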