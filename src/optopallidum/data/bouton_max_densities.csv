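animal_id,cortical_source,region,ml_position,count,roi_width,roi_height
m1_rat1,M1,GP,,267,100,100
m1_rat2,M1,GP,,200,100,100
m1_rat3,M1,GP,,289,100,100
m1_rat4,M1,GP,,141,100,100
m1_rat1,M1,CPu,,911,100,100
m1_rat2,M1,CPu,,1300,100,100
m1_rat3,M1,CPu,,1464,100,100
m1_rat4,M1,CPu,,657,100,100
m1_rat1,M1,STN,,506,100,100
m1_rat2,M1,STN,,432,100,100
m1_rat3,M1,STN,,528,100,100
m1_rat4,M1,STN,,408,100,100
m2_rat1,M2,GP,,317,100,100
m2_rat2,M2,GP,,737,100,100
m2_rat3,M2,GP,,513,100,100
m2_rat4,M2,GP,,92,100,100
m2_rat1,M2,CPu,,1300,100,100
m2_rat2,M2,CPu,,2021,100,100
m2_rat3,M2,CPu,,1829,100,100
m2_rat4,M2,CPu,,398,100,100
m2_rat1,M2,STN,,420,100,100
m2_rat2,M2,STN,,717,100,100
m2_rat3,M2,STN,,637,100,100
m2_rat4,M2,STN,,177,100,100
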