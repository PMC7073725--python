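compound,ri_wax,ri_db5,descriptor,fd_HHL,fd_ZPL,fd_LPLJ
Ethyl acetate,897,638,Pineapple,64,512,64
Ethyl propionate,967,726,Banana,16,32,16
Ethyl 2-methylpropionate,974,773,"Sweet, rubber",128,256,256
Propyl acetate,983,,Fruity,1,1,1
Isobutyl acetate,1020,788,"Fruity, banana",2,1,1
Ethyl butyrate,1045,815,Apple,256,256,256
Ethyl 2-methylbutyrate,1059,863,Apple,128,256,256
Ethyl 3-methylbutyrate,1074,868,Fruity,256,256,256
Isoamyl acetate,1127,890,Banana,16,16,16
Ethyl valerate,1141,914,Apple,128,256,256
Butyl butyrate,1222,,"Banana, pineapple",8,4,4
Ethyl hexanoate,1246,1017,Apple peel fruit,1024,1024,1024
Isoamyl butyrate,1278,1072,Green apple,1,1,1
Propyl hexanoate,1324,1109,Pineapple,1,1,1
Ethyl heptanoate,1342,1113,Fruity,4,4,4
Ethyl lactate,1350,830,Green fruity,16,16,16
Ethyl caprylate,1443,1213,"Fruity, fat",512,128,128
Isopentyl hexanoate,1465,1268,Pineapple,1,1,1
Ethyl nonanoate,1542,,Fruity,4,4,4
Hexyl hexanoate,1616,1404,Vegetable fruity,1,nd,1
Ethyl 2-furoate,1634,1069,"Floral, burnt",2,2,2
Ethyl caprate,,1113,Fruity,16,8,8
Ethyl benzoate,1684,1189,Floral,8,8,8
Ethyl phenylacetate,1801,1263,"Rosy, honey",32,32,32
Ethyl laurate,1851,1617,"Waxy, floral",16,16,16
Ethyl 3-phenylpropionate,1904,1369,"Fruity, floral, wine",32,32,16
Ethyl tetradecanoate,2056,1782,Floral,1,1,nd
Ethyl pentadecanoate,2109,1884,Honey sweet,4,4,4
Ethyl palmitate,2265,2023,"Fruity, creamy",16,16,16
Ethyl oleate,2468,2200,Fatty,16,16,16
Ethyl linoleate,2512,2194,Fatty,8,16,1
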