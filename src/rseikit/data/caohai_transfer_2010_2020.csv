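from_class,water,construction,grassland,cultivated,forest,unused
water,22.209,0.023,0.068,0.001,0.726,0.000
construction,0.002,3.058,1.252,0.014,0.189,0.053
grassland,0.096,2.559,32.284,1.556,3.286,0.833
cultivated,0.443,2.388,8.609,0.864,2.317,0.127
forest,0.714,0.651,3.452,0.050,7.219,0.008
unused,0.004,0.356,2.753,0.066,0.036,0.995
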