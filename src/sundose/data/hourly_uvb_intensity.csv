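month,hour_start,intensity_w_m2
September,0,0
September,1,0
September,2,0
September,3,0
September,4,0
September,5,0
September,6,0.2
September,7,4.9
September,8,5.7
September,9,7.8
September,10,9.9
September,11,9.7
September,12,9.7
September,13,8
September,14,7.4
September,15,5.9
September,16,5.6
September,17,1.3
September,18,0
September,19,0
September,20,0
September,21,0
September,22,0
September,23,0
October,0,0
October,1,0
October,2,0
October,3,0
October,4,0
October,5,0
October,6,0.9
October,7,4
October,8,5.7
October,9,8.2
October,10,11
October,11,12
October,12,10
October,13,9.4
October,14,7.1
October,15,5.9
October,16,3.3
October,17,1
October,18,0
October,19,0
October,20,0
October,21,0
October,22,0
October,23,0
November,0,0
November,1,0
November,2,0
November,3,0
November,4,0
November,5,0
November,6,1.2
November,7,2.7
November,8,4.1
November,9,6.5
November,10,9
November,11,8.6
November,12,8.9
November,13,8
November,14,6.1
November,15,3.9
November,16,3.4
November,17,1.2
November,18,0
November,19,0
November,20,0
November,21,0
November,22,0
November,23,0
December,0,0
December,1,0
December,2,0
December,3,0
December,4,0
December,5,0
December,6,0.7
December,7,3.7
December,8,5.2
December,9,7.5
December,10,9.7
December,11,12
December,12,13
December,13,12
December,14,9
December,15,6.6
December,16,4.1
December,17,3.5
December,18,0
December,19,0
December,20,0
December,21,0
December,22,0
December,23,0
January,0,0
January,1,0
January,2,0
January,3,0
January,4,0
January,5,0
January,6,0.01
January,7,0.18
January,8,0.3
January,9,0.47
January,10,0.63
January,11,0.67
January,12,0.63
January,13,0.54
January,14,0.45
January,15,0.3
January,16,0.16
January,17,0.06
January,18,0
January,19,0
January,20,0
January,21,0
January,22,0
January,23,0
February,0,0
February,1,0
February,2,0
February,3,0
February,4,0
February,5,0
February,6,0.47
February,7,2.99
February,8,3.85
February,9,6.95
February,10,9.65
February,11,11.9
February,12,12.7
February,13,11
February,14,8.16
February,15,5.39
February,16,3.01
February,17,1.02
February,18,0
February,19,0
February,20,0
February,21,0
February,22,0
February,23,0
March,0,0
March,1,0
March,2,0
March,3,0
March,4,0
March,5,0
March,6,3.37
March,7,6.35
March,8,7.79
March,9,10.4
March,10,12.6
March,11,13.5
March,12,13.3
March,13,11.2
March,14,9.75
March,15,7.34
March,16,5.35
March,17,1.42
March,18,0
March,19,0
March,20,0
March,21,0
March,22,0
March,23,0
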