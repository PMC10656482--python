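from_class,water,construction,grassland,cultivated,forest,unused
water,21.614,0.013,0.033,0.001,0.313,0.000
construction,0.356,1.247,0.404,0.006,0.282,0.017
grassland,0.376,5.129,33.732,1.715,3.623,0.909
cultivated,0.242,1.396,8.265,0.711,2.732,0.141
forest,0.879,1.189,3.295,0.020,6.755,0.014
unused,0.000,0.060,2.688,0.097,0.068,0.934
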