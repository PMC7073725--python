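mixture_id,component_1,component_2,oav_mix,oav_1,oav_2,sum_oav,x,interaction
C2C2+2MeC4C2,Ethyl acetate,Ethyl 2-methylbutyrate,38.01,1.32,21.01,22.33,0.59,additive effect
C2C2+Ci5C2,Ethyl acetate,Ethyl 3-methylbutyrate,579.29,1.32,131.75,133.06,0.23,synergistic effect
C2C2+C6C2,Ethyl acetate,Ethyl hexanoate,28.74,1.32,3.53,4.84,0.17,synergistic effect
C2C2+C2BeC2,Ethyl acetate,Ethyl phenylacetate,9.39,1.32,0.79,2.11,0.22,synergistic effect
2MeC4C2+Ci5C2,Ethyl 2-methylbutyrate,Ethyl 3-methylbutyrate,733.62,21.01,131.75,152.75,0.21,synergistic effect
2MeC4C2+C6C2,Ethyl 2-methylbutyrate,Ethyl hexanoate,99.28,21.01,3.53,24.53,0.25,synergistic effect
2MeC4C2+C2BeC2,Ethyl 2-methylbutyrate,Ethyl phenylacetate,204.40,21.01,0.79,21.80,0.11,synergistic effect
Ci5C2+C6C2,Ethyl 3-methylbutyrate,Ethyl hexanoate,388.68,131.75,3.53,135.27,0.35,synergistic effect
Ci5C2+C2BeC2,Ethyl 3-methylbutyrate,Ethyl phenylacetate,548.80,131.75,0.79,132.54,0.24,synergistic effect
C6C2+C2BeC2,Ethyl hexanoate,Ethyl phenylacetate,15.58,3.53,0.79,4.32,0.28,synergistic effect
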