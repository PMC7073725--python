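compound,threshold,threshold_source,oav_HHL,oav_ZPL,oav_LPLJ
Ethyl acetate,32600,46% ethanol/water,15,16,14
Ethyl propionate,19000,46% ethanol/water,2,2,2
Ethyl 2-methylpropionate,57.5,46% ethanol/water,170,179,168
Propyl acetate,4740,literature compilation,<1,<1,<1
Isobutyl acetate,922,46% ethanol/water,<1,<1,<1
Ethyl butyrate,81.5,46% ethanol/water,289,319,336
Ethyl 2-methylbutyrate,18,46% ethanol/water,220,219,210
Ethyl 3-methylbutyrate,6.89,46% ethanol/water,1857,1801,1686
Isoamyl acetate,93.93,46% ethanol/water,31,31,29
Ethyl valerate,26.8,46% ethanol/water,333,366,389
Butyl butyrate,110,literature compilation,2,2,2
Ethyl hexanoate,55.3,46% ethanol/water,250,109,178
Isoamyl butyrate,20,literature compilation,15,13,13
Propyl hexanoate,12783.77,46% ethanol/water,<1,<1,<1
Ethyl heptanoate,13200,46% ethanol/water,<1,<1,<1
Ethyl lactate,128000,46% ethanol/water,3,3,3
Ethyl caprylate,12.9,46% ethanol/water,212,228,217
Isopentyl hexanoate,1400,46% ethanol/water,<1,<1,<1
Ethyl nonanoate,3150,46% ethanol/water,<1,<1,<1
Ethyl caprate,1120,46% ethanol/water,1,<1,<1
Ethyl benzoate,1430,46% ethanol/water,<1,<1,<1
Ethyl phenylacetate,407,46% ethanol/water,4,5,5
Ethyl laurate,1500,literature compilation,<1,<1,<1
Ethyl 3-phenylpropionate,125,46% ethanol/water,3,4,4
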