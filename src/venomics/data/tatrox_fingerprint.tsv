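rt_start	rt_end	mass
1	20	1462.7
1	20	2057.24
1	20	2117.68
1	20	2265.06
1	20	2796.27
1	20	3111.96
1	20	9115.86
1	20	10663.93
1	20	11123.28
20	40	1076.62
20	40	1205.68
20	40	1212.80
20	40	1673.85
20	40	1817.88
20	40	3427.38
20	40	3499.92
20	40	3586.92
20	40	3878.10
20	40	4197.53
20	40	12306.36
40	60	1331.64
40	60	1799.04
40	60	1886.82
40	60	2333.32
40	60	2411.36
40	60	2447.40
40	60	2592.26
40	60	3777.63
40	60	3945.62
40	60	5813.52
60	80	2377.16
60	80	2850.1
60	80	2944.70
60	80	3606.60
60	80	4485.10
60	80	4595.04
60	80	5279.52
60	80	5654.40
80	100	3332.90
80	100	3535.47
80	100	3718.60
80	100	3787.85
80	100	4113.96
80	100	4125.80
80	100	4204.00
80	100	4279.05
80	100	4290.36
80	100	5196.42
80	100	5756.56
80	100	7011.33
80	100	7123.96
80	100	7236.99
80	100	8126.40
80	100	8328.51
100	120	3223.80
100	120	3243.80
100	120	3569.92
100	120	3767.15
100	120	4250.67
100	120	8468.54
100	120	8581.60
100	120	8716.70
100	120	9056.88
100	120	9490.25
120	140	1198.64
120	140	1648.86
120	140	3267.39
120	140	4036.16
120	140	4348.40
120	140	4561.84
120	140	4815.2
140	160	1944.15
140	160	2645.50
140	160	2815.60
140	160	6330.03
140	160	6473.90
140	160	6714.40
140	160	7438.62
140	160	7639.27
140	160	7843.00
140	160	8049.12
140	160	8213.16
140	160	8829.81
140	160	8950.11
140	160	9535.2
160	180	1337.72
160	180	1497.81
160	180	2193.06
160	180	2248.28
160	180	2347.32
160	180	3338.30
160	180	7040.46
160	180	7956.10
160	180	8201.97
160	180	8727.14
180	200	1296.10
180	200	2151.20
180	200	4171.38
180	200	4302.42
180	200	4389.42
180	200	4697.56
180	200	4762.08
180	200	6195.66
200	220	10039.5
200	220	13729.41
200	220	14079.03
220	240	1828.00
220	240	6554.31
220	240	6750.45
220	240	6946.57
220	240	7269.84
220	240	8272.50
220	240	10545.20
220	240	12430.9
220	240	13591.92
220	240	13815.51
220	240	14614.72
240	260	3821.44
240	260	5409.48
240	260	10882.9
240	260	16915.41
260	290	2038.11
260	290	3347.5
260	290	4505.55
260	290	4791.65
260	290	4949.7
260	290	8355.48
260	290	11174.46
260	290	11833.92
260	290	11847.44
260	290	11899.27
260	290	13891.59
260	290	14257.71
260	290	14705.56
260	290	14741.70
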