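name	lo_cm1	hi_cm1	is_amide1
amide_A_B	3000.0	3600.0	false
ch_stretch_high	2900.0	3000.0	false
ch_stretch_low	2800.0	2900.0	false
amide_I	1585.0	1762.0	true
amide_II	1473.0	1585.0	false
collagen_1337	1325.0	1346.0	false
carb_1140_1180	1140.0	1180.0	false
dna_rna_980_1180	980.0	1180.0	false
fp_900_917	900.0	916.9	false
fp_917_934	916.9	933.7	false
fp_934_951	933.7	950.6	false
fp_951_967	950.6	967.4	false
fp_967_984	967.4	984.3	false
fp_984_1001	984.3	1001.1	false
fp_1001_1018	1001.1	1018.0	false
fp_1018_1035	1018.0	1034.8	false
fp_1035_1052	1034.8	1051.7	false
fp_1052_1068	1051.7	1068.5	false
fp_1068_1085	1068.5	1085.4	false
fp_1085_1102	1085.4	1102.2	false
fp_1102_1119	1102.2	1119.1	false
fp_1119_1136	1119.1	1135.9	false
fp_1136_1153	1135.9	1152.8	false
fp_1153_1170	1152.8	1169.6	false
fp_1170_1186	1169.6	1186.5	false
fp_1186_1203	1186.5	1203.4	false
fp_1203_1220	1203.4	1220.2	false
fp_1220_1237	1220.2	1237.1	false
fp_1237_1254	1237.1	1253.9	false
fp_1254_1271	1253.9	1270.8	false
fp_1271_1288	1270.8	1287.6	false
fp_1288_1304	1287.6	1304.5	false
fp_1304_1321	1304.5	1321.3	false
fp_1321_1338	1321.3	1338.2	false
fp_1338_1355	1338.2	1355.0	false
fp_1355_1372	1355.0	1371.9	false
fp_1372_1389	1371.9	1388.7	false
fp_1389_1406	1388.7	1405.6	false
fp_1406_1422	1405.6	1422.4	false
fp_1422_1439	1422.4	1439.3	false
fp_1439_1456	1439.3	1456.1	false
fp_1456_1473	1456.1	1473.0	false
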