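code,chronic,body_system
042,1,1
070.54,1,1
034.0,0,1
153.9,1,2
174.9,1,2
185,1,2
244.9,1,3
250.00,1,3
250.01,1,3
250.02,1,3
272.4,1,3
282.60,1,4
285.21,1,4
285.1,0,4
296.30,1,5
303.90,1,5
309.81,1,5
300.00,0,5
332.0,1,6
332.1,1,6
340,1,6
365.11,1,6
389.10,1,6
389.15,1,6
389.18,1,6
401.9,1,7
414.01,1,7
427.31,1,7
428.0,1,7
785.1,0,7
491.21,1,8
493.20,1,8
496,1,8
486,0,8
530.81,1,9
571.5,1,9
562.10,0,9
585.6,1,10
585.9,1,10
600.00,1,10
599.0,0,10
642.03,1,11
696.1,1,12
707.00,1,12
680.9,0,12
714.0,1,13
715.90,1,13
721.90,1,13
845.00,0,13
745.4,1,14
745.5,1,14
770.7,1,15
765.10,1,15
780.71,1,16
780.2,0,16
907.2,1,17
905.0,1,17
884.0,0,17
V58.61,1,18
V45.01,1,18
V70.0,0,18
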