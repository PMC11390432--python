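# Per-subject segmentation scores (DSC/SEN/PPV) for five models on a 20-patient T2-weighted cohort.
# Columns are metric:model; rows are subjects 1-20.
subject_id,DSC:IAANet,DSC:TriSegNet,DSC:U-Net,DSC:nnU-Net,DSC:MfNS_De,SEN:IAANet,SEN:TriSegNet,SEN:U-Net,SEN:nnU-Net,SEN:MfNS_De,PPV:IAANet,PPV:TriSegNet,PPV:U-Net,PPV:nnU-Net,PPV:MfNS_De
1,0.492,0.643,0.694,0.722,0.714,0.577,0.689,0.666,0.802,0.631,0.429,0.603,0.724,0.656,0.821
2,0.510,0.596,0.720,0.687,0.737,0.661,0.492,0.673,0.609,0.755,0.415,0.755,0.774,0.788,0.717
3,0.458,0.533,0.676,0.678,0.703,0.435,0.843,0.804,0.838,0.633,0.483,0.390,0.583,0.570,0.793
4,0.431,0.574,0.640,0.677,0.685,0.519,0.710,0.617,0.816,0.630,0.369,0.482,0.664,0.579,0.717
5,0.498,0.662,0.646,0.652,0.675,0.432,0.669,0.535,0.522,0.649,0.587,0.654,0.816,0.869,0.697
6,0.412,0.555,0.642,0.668,0.718,0.445,0.780,0.627,0.614,0.786,0.383,0.431,0.658,0.732,0.665
7,0.491,0.611,0.636,0.630,0.683,0.442,0.580,0.598,0.548,0.679,0.551,0.645,0.680,0.741,0.682
8,0.409,0.313,0.629,0.651,0.671,0.431,0.535,0.645,0.559,0.651,0.389,0.221,0.613,0.779,0.701
9,0.561,0.647,0.732,0.753,0.711,0.493,0.544,0.689,0.693,0.630,0.651,0.797,0.781,0.824,0.803
10,0.617,0.582,0.649,0.676,0.703,0.729,0.605,0.662,0.737,0.750,0.535,0.561,0.637,0.624,0.740
11,0.600,0.500,0.580,0.630,0.699,0.636,0.376,0.472,0.527,0.645,0.567,0.745,0.752,0.785,0.775
12,0.581,0.538,0.581,0.591,0.675,0.613,0.452,0.488,0.486,0.634,0.552,0.665,0.719,0.752,0.735
13,0.445,0.598,0.659,0.690,0.663,0.541,0.622,0.643,0.667,0.600,0.378,0.575,0.677,0.714,0.726
14,0.374,0.568,0.649,0.715,0.687,0.460,0.744,0.709,0.763,0.659,0.315,0.459,0.597,0.674,0.726
15,0.411,0.576,0.646,0.667,0.691,0.562,0.563,0.717,0.717,0.678,0.323,0.589,0.589,0.624,0.702
16,0.474,0.673,0.700,0.776,0.745,0.621,0.792,0.744,0.822,0.706,0.383,0.585,0.661,0.735,0.770
17,0.431,0.681,0.706,0.733,0.750,0.525,0.655,0.715,0.716,0.706,0.365,0.709,0.696,0.750,0.799
18,0.425,0.654,0.665,0.695,0.702,0.542,0.697,0.723,0.796,0.675,0.350,0.616,0.616,0.617,0.733
19,0.484,0.674,0.715,0.710,0.744,0.535,0.696,0.732,0.643,0.738,0.441,0.654,0.699,0.792,0.751
20,0.439,0.608,0.649,0.666,0.686,0.551,0.656,0.742,0.668,0.618,0.365,0.567,0.576,0.664,0.769
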