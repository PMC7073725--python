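test_id,omitted_compound,stars
Test 1,Ethyl acetate,***
Test 2,Ethyl propionate,**
Test 3,Ethyl 2-methylpropionate,*
Test 4,Ethyl butyrate,**
Test 5,Ethyl 2-methylbutyrate,***
Test 6,Ethyl 3-methylbutyrate,***
Test 7,Isoamyl acetate,*
Test 8,Ethyl valerate,**
Test 9,Ethyl hexanoate,***
Test 10,Ethyl caprylate,**
Test 11,Ethyl caprate,=
Test 12,Ethyl phenylacetate,***
Test 13,Ethyl 3-phenylpropionate,**
Test 14,Ethyl lactate,**
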