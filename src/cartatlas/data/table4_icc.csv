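parameter,modality,rater,icc,ci_low,ci_high
ML,MRI,1,0.986,0.953,0.997
ML,MRI,2,0.992,0.976,0.998
ML,MRI,3,0.947,0.841,0.987
ML,MRI,4,0.972,0.916,0.993
ML,CT,1,0.981,0.945,0.995
ML,CT,2,0.954,0.870,0.988
ML,CT,3,0.967,0.904,0.992
ML,CT,4,0.818,0.514,0.919
AP medial,MRI,1,0.939,0.829,0.985
AP medial,MRI,2,0.737,0.414,0.925
AP medial,MRI,3,0.899,0.635,0.976
AP medial,MRI,4,0.818,0.643,0.951
AP medial,CT,1,0.861,0.426,0.969
AP medial,CT,2,0.917,0.770,0.979
AP medial,CT,3,0.800,0.548,0.934
AP medial,CT,4,0.892,0.688,0.973
AP lateral,MRI,1,0.919,0.771,0.979
AP lateral,MRI,2,0.973,0.922,0.993
AP lateral,MRI,3,0.861,0.337,0.970
AP lateral,MRI,4,0.685,0.285,0.871
AP lateral,CT,1,0.870,0.430,0.971
AP lateral,CT,2,0.946,0.846,0.986
AP lateral,CT,3,0.963,0.889,0.991
AP lateral,CT,4,0.975,0.927,0.994
JSW medial,MRI,1,0.943,0.840,0.985
JSW medial,MRI,2,0.959,0.881,0.990
JSW medial,MRI,3,0.620,0.232,0.885
JSW medial,MRI,4,0.818,0.487,0.918
JSW medial,CT,1,0.883,0.691,0.969
JSW medial,CT,2,0.731,0.401,0.924
JSW medial,CT,3,0.857,0.640,0.962
JSW medial,CT,4,0.763,0.538,0.931
JSW lateral,MRI,1,0.803,0.515,0.947
JSW lateral,MRI,2,0.970,0.913,0.992
JSW lateral,MRI,3,0.726,0.400,0.921
JSW lateral,MRI,4,0.666,0.266,0.852
JSW lateral,CT,1,0.736,0.416,0.924
JSW lateral,CT,2,0.974,0.924,0.994
JSW lateral,CT,3,0.840,0.604,0.957
JSW lateral,CT,4,0.851,0.627,0.960
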