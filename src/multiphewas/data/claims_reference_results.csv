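age_bin,phenotype,category,or_fvsm,ci_low_fvsm,ci_high_fvsm,or_asdvsnon,ci_low_asdvsnon,ci_high_asdvsnon
0-2,Other specified congenital anomalies of nervous system,congenital anomalies,3.386,2.048,5.588,12.016,8.258,16.941
0-2,Failure to thrive (childhood),endocrine/metabolic,2.499,1.807,3.438,4.498,3.484,5.724
0-2,"Symptoms concerning nutrition, metabolism, and development",symptoms,1.708,1.375,2.115,4.74,3.949,5.652
3-5,Other cerebral degenerations,neurological,12.543,5.481,32.206,72.042,44.257,113.241
3-5,Other specified congenital anomalies of nervous system,congenital anomalies,2.991,2.109,4.223,24.262,18.309,31.617
3-5,"Epilepsy, recurrent seizures, convulsions",neurological,2.126,1.653,2.719,34.544,27.822,42.634
3-5,Epilepsy,neurological,2.07,1.542,2.759,32.671,25.301,41.628
3-5,Chromosomal anomalies,congenital anomalies,2.033,1.544,2.66,15.01,11.892,18.731
3-5,Partial epilepsy,neurological,2.013,1.518,2.65,31.128,24.352,39.279
3-5,Strabismus (not specified as paralytic),sense organs,1.936,1.586,2.357,4.958,4.192,5.829
3-5,Convulsions,neurological,1.916,1.618,2.263,22.899,19.772,26.377
3-5,Constipation,digestive,1.744,1.463,2.071,6.715,5.78,7.765
6-11,Other cerebral degenerations,neurological,20.083,8.734,53.75,50.25,33.36,73.628
6-11,Dementias,mental disorders,15.307,5.476,52.777,120.02,64.072,217.684
6-11,Chromosomal anomalies,congenital anomalies,2.562,2.144,3.055,25.225,21.715,29.167
6-11,"Epilepsy, recurrent seizures, convulsions",neurological,2.178,1.86,2.545,33.37,29.055,38.152
6-11,Other specified congenital anomalies of nervous system,congenital anomalies,2.174,1.666,2.821,24.521,19.482,30.516
6-11,Other and unspecified congenital anomalies,congenital anomalies,2.163,1.614,2.877,18.506,14.415,23.439
6-11,Epilepsy,neurological,2.122,1.749,2.566,23.497,19.877,27.574
6-11,Partial epilepsy,neurological,2.037,1.726,2.397,27.776,24.032,31.934
6-11,Generalized convulsive epilepsy,neurological,1.999,1.581,2.516,31.497,25.573,38.416
6-11,Infantile cerebral palsy,neurological,1.983,1.611,2.432,16.813,14.056,19.978
6-11,Intellectual disability,mental disorders,1.934,1.651,2.259,131.481,111.943,153.279
6-11,Strabismus (not specified as paralytic),sense organs,1.834,1.599,2.1,5.306,4.718,5.948
6-11,Convulsions,neurological,1.791,1.589,2.017,23.617,21.217,26.182
6-11,Abdominal pain,symptoms,1.741,1.525,1.985,2.056,1.835,2.297
6-11,GERD,digestive,1.721,1.436,2.056,7.853,6.715,9.133
6-11,Fever of unknown origin,symptoms,1.69,1.489,1.916,2.505,2.245,2.787
6-11,Constipation,digestive,1.632,1.448,1.838,7.785,7.012,8.625
12-18,Dementias,mental disorders,15.899,4.289,87.753,82.438,39.601,158.28
12-18,Other cerebral degenerations,neurological,14.238,5.984,39.011,54.069,33.839,83.481
12-18,Other and unspecified congenital anomalies,congenital anomalies,2.542,1.867,3.444,28.54,22.088,36.367
12-18,Dehydration,endocrine/metabolic,2.499,1.743,3.554,4.604,3.448,6.03
12-18,Chromosomal anomalies,congenital anomalies,2.482,2.009,3.059,27.246,22.863,32.274
12-18,Insomnia,neurological,1.964,1.499,2.556,10.151,8.087,12.587
12-18,Strabismus (not specified as paralytic),sense organs,1.894,1.539,2.323,8.487,7.122,10.042
12-18,Epilepsy,neurological,1.866,1.51,2.298,25.823,21.486,30.794
12-18,Infantile cerebral palsy,neurological,1.817,1.456,2.257,21.134,17.458,25.391
12-18,Intellectual disability,mental disorders,1.783,1.568,2.023,162.89,141.49,184.347
12-18,Developmental delays and disorders,mental disorders,1.745,1.558,1.952,76.338,68.867,84.751
12-18,Muscle weakness,musculoskeletal,1.706,1.377,2.105,3.355,2.797,3.994
12-18,"Epilepsy, recurrent seizures, convulsions",neurological,1.696,1.455,1.973,30.268,26.447,34.559
12-18,"Lack of normal physiological development, unspecified",symptoms,1.671,1.404,1.983,71.896,61.121,83.963
12-18,Dysthymic disorder,mental disorders,1.659,1.393,1.971,4.532,3.903,5.236
12-18,Myopia,sense organs,1.637,1.325,2.014,1.765,1.474,2.098
12-18,Urinary incontinence,genitourinary,1.627,1.376,1.918,24.359,21.014,28.085
12-18,Partial epilepsy,neurological,1.598,1.349,1.887,28.837,24.812,33.374
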