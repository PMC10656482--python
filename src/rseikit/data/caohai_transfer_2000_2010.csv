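from_class,water,construction,grassland,cultivated,forest,unused
water,21.421,0.007,0.000,0.164,0.382,0.000
construction,0.472,1.574,0.068,0.064,0.133,0.002
grassland,0.541,2.286,29.890,8.017,2.524,2.227
cultivated,0.021,0.321,6.378,4.780,1.866,0.122
forest,0.572,0.370,2.335,1.679,7.190,0.006
unused,0.000,0.009,1.942,0.043,0.000,1.854
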