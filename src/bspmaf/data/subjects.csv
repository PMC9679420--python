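id,age,sex,recurrence,segments
13,53,Male,No,72
14,52,Male,No,106
16,50,Male,No,86
17,50,Male,No,82
18,69,Male,Yes,69
19,46,Female,Yes,62
20,44,Female,No,68
21,50,Female,No,74
22,46,Male,No,91
23,65,Female,No,70
24,42,Female,Yes,108
25,62,Female,No,88
26,43,Female,No,76
30,50,Female,Yes,120
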