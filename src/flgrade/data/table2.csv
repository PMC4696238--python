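case,consensus_grade,n_detected,n_high,n_low,percent_high,computer_grade
1,HIGH,826,755,71,91.4,HIGH
2,HIGH,324,320,4,98.8,HIGH
3,HIGH,98,98,0,100.0,HIGH
4,HIGH,56,55,1,98.2,HIGH
5,HIGH,66,66,0,100.0,HIGH
6,HIGH,154,154,0,100.0,HIGH
7,HIGH,208,207,1,99.5,HIGH
8,HIGH,123,120,3,97.6,HIGH
9,HIGH,742,330,412,44.5,LOW
10,HIGH,102,6,96,5.9,LOW
11,LOW,361,273,88,75.6,HIGH
12,LOW,187,186,1,99.5,HIGH
13,LOW,67,17,50,25.4,LOW
14,LOW,390,99,291,25.4,LOW
15,LOW,199,82,117,41.2,LOW
16,LOW,46,1,45,2.2,LOW
17,LOW,25,2,23,8.0,LOW
18,LOW,191,27,164,14.1,LOW
19,LOW,169,0,169,0.0,LOW
20,LOW,36,0,36,0.0,LOW
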