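age_bin,phenotype,category,or_fvsm,ci_low_fvsm,ci_high_fvsm,or_asdvsnon,ci_low_asdvsnon,ci_high_asdvsnon
3-5,Delayed milestones,mental disorders,3.458,2.029,5.859,8.907,5.563,13.943
6-11,Other cerebral degenerations,neurological,14.035,4.387,58.8,9.824,4.734,19.525
6-11,Epilepsy,neurological,3.363,2.196,5.125,5.306,3.69,7.501
6-11,Chromosomal anomalies,congenital anomalies,2.32,1.698,3.151,5.86,4.408,7.719
6-11,"Epilepsy, recurrent seizures, convulsions",neurological,2.263,1.577,3.219,5.425,3.906,7.433
6-11,Convulsions,neurological,2.19,1.61,2.961,5.173,3.915,6.771
6-11,Developmental delays and disorders,mental disorders,1.694,1.357,2.111,10.984,8.886,13.56
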