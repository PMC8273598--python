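scope,parameter,isometric_slope,slope,ci_low,ci_high,r2,intercept,p,category
Whole sample,BV/TV,0,1.800,1.440,2.250,0.133,-2.550,0.001,Positive
Whole sample,DA,0,-0.759,-0.966,-0.596,0.005,0.310,0.559,Uncorrelated
Whole sample,Tb.Th,1,1.480,1.240,1.770,0.460,-2.280,<0.001,Positive
Whole sample,Tb.N,0,-1.140,-1.390,-0.940,0.362,1.360,<0.001,Negative
Whole sample,Tb.Sp,1,1.290,1.040,1.600,0.187,-1.680,<0.001,Positive
Whole sample,Total BV/TV,0,1.830,1.460,2.280,0.150,-2.420,0.001,Positive
Whole sample,Ct.Th,1,2.430,1.980,2.980,0.278,-3.160,<0.001,Positive
Homo,BV/TV,0,2.600,1.760,3.840,0.095,-3.510,0.125,Uncorrelated
Homo,DA,0,1.190,0.799,1.760,0.068,-1.880,0.198,Uncorrelated
Homo,Tb.Th,1,1.970,1.370,2.810,0.244,-2.860,0.010,Positive
Homo,Tb.N,0,-1.630,-2.420,-1.100,0.066,1.900,0.205,Uncorrelated
Homo,Tb.Sp,1,1.990,1.320,2.990,0.009,-2.440,0.629,Uncorrelated
Homo,Total BV/TV,0,2.160,1.450,3.210,0.064,-2.880,0.212,Uncorrelated
Homo,Ct.Th,1,1.980,1.370,2.870,0.194,-2.760,0.024,Positive
Pan,BV/TV,0,-1.770,-3.140,-0.998,0.070,1.550,0.341,Uncorrelated
Pan,DA,0,1.390,0.785,2.470,0.070,-2.160,0.344,Uncorrelated
Pan,Tb.Th,1,-1.520,-2.710,-0.850,0.068,1.100,0.384,Uncorrelated
Pan,Tb.N,0,1.140,0.628,2.060,<0.001,-1.170,0.976,Uncorrelated
Pan,Tb.Sp,1,1.480,0.823,2.680,0.011,-1.950,0.071,Uncorrelated
Pan,Total BV/TV,0,-1.850,-3.310,-1.030,0.032,1.800,0.536,Uncorrelated
Pan,Ct.Th,1,-2.230,-4.000,-1.250,0.040,2.230,0.493,Uncorrelated
Gorilla,BV/TV,0,-1.010,-1.720,-0.597,0.064,0.859,0.342,Uncorrelated
Gorilla,DA,0,0.712,0.418,1.210,0.050,-1.450,0.403,Uncorrelated
Gorilla,Tb.Th,1,0.959,0.678,1.360,0.618,-1.650,<0.001,Isometry
Gorilla,Tb.N,0,-1.220,-1.670,-0.895,0.693,1.490,<0.001,Negative
Gorilla,Tb.Sp,1,1.450,1.020,2.070,0.602,-1.940,<0.001,Positive
Gorilla,Total BV/TV,0,-0.833,-1.430,-0.484,0.011,0.802,0.698,Uncorrelated
Gorilla,Ct.Th,1,1.670,1.080,2.560,0.402,-2.280,0.008,Positive
Pongo,BV/TV,0,2.570,1.410,4.690,0.077,-3.320,0.358,Uncorrelated
Pongo,DA,0,-1.180,-2.010,-0.690,0.291,0.761,0.057,Uncorrelated
Pongo,Tb.Th,1,1.690,1.010,2.850,0.328,-2.440,0.040,Positive
Pongo,Tb.N,0,-1.030,-1.880,-0.567,0.079,1.180,0.351,Uncorrelated
Pongo,Tb.Sp,1,1.330,0.711,2.470,<0.001,-1.660,0.980,Uncorrelated
Pongo,Total BV/TV,0,2.040,1.160,3.580,0.203,-2.560,0.123,Uncorrelated
Pongo,Ct.Th,1,3.250,2.000,5.280,0.425,-3.940,0.015,Positive
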