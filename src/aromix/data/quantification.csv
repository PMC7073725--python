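compound,quant_ion,slope,intercept,r_squared,conc_HHL,rsd_HHL,conc_ZPL,rsd_ZPL,conc_LPLJ,rsd_LPLJ
Ethyl acetate,43,0.062,0.0475,0.991,488275,6,529294,4,450892,7
Ethyl propionate,57,0.215,-0.0517,0.996,32654,3,35598,3,35567,5
Ethyl 2-methylpropionate,43,0.406,-0.0682,0.992,9803,5,10305,3,9664,9
Propyl acetate,43,0.259,-0.0042,0.996,3831,8,4625,4,3263,6
Isobutyl acetate,43,0.665,-0.0061,0.996,541,4,576,6,514,6
Ethyl butyrate,71,0.427,-0.1793,0.995,23585,3,25975,7,27387,5
Ethyl 2-methylbutyrate,57,1.168,-0.1376,0.993,3961,3,3944,9,3792,5
Ethyl 3-methylbutyrate,88,0.6,-0.1378,0.995,12795,6,12412,6,11615,5
Isoamyl acetate,43,1.169,-0.0989,0.996,2872,4,2892,5,2745,2
Ethyl valerate,88,0.886,-0.1134,0.994,8922,5,9817,5,10438,2
Butyl butyrate,71,2.857,-0.0373,0.991,207,5,184,4,189,9
Ethyl hexanoate,88,1.43,-0.6541,1.000,13849,4,6078,3,9868,3
Isoamyl butyrate,71,4.816,-0.0715,0.993,293,6,262,5,267,5
Propyl hexanoate,99,3.705,-0.0736,0.996,775,7,548,2,545,5
Ethyl heptanoate,88,3.801,-0.406,1.000,6404,1,4215,6,4378,6
Ethyl lactate,45,0.016,0.0133,0.994,340025,6,414676,8,428330,5
Ethyl caprylate,88,5.104,-0.1023,0.993,2733,6,2938,2,2801,3
Isopentyl hexanoate,70,11.64,-0.099,0.999,454,7,202,6,188,7
Ethyl nonanoate,88,9.773,-0.1131,0.999,174,5,197,3,155,5
Hexyl hexanoate,117,9.222,-0.0604,0.998,287,4,nd,,123,9
Ethyl 2-furoate,95,0.695,0.0004,0.999,1608,6,2013,3,1429,4
Ethyl caprate,88,12.08,-0.2581,0.999,1311,7,336,7,318,6
Ethyl benzoate,105,5.3,-0.0488,0.998,320,5,316,5,360,3
Ethyl phenylacetate,91,5.723,-0.016,0.993,1699,4,2007,4,1842,6
Ethyl laurate,88,8.637,-0.3412,1.000,898,4,598,3,567,4
Ethyl 3-phenylpropionate,104,6.304,-0.065,0.998,418,4,457,6,482,4
Ethyl tetradecanoate,88,2.621,-0.0099,1.000,699,5,568,5,nd,
Ethyl pentadecanoate,88,1.274,-0.024,0.998,543,4,1135,4,562,5
Ethyl palmitate,88,0.467,0.1301,0.998,17021,6,17391,4,2507,7
Ethyl oleate,55,0.743,0.0004,0.997,606,8,530,2,141,3
Ethyl linoleate,67,0.123,-0.0003,0.996,2521,4,40743,7,222,5
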