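class,2000,2010,2020
water,21.974,23.027,23.468
construction,2.313,4.568,9.034
grassland,45.484,40.613,48.417
cultivated,13.487,14.747,2.551
forest,12.152,12.094,13.773
unused,3.848,4.210,2.016
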