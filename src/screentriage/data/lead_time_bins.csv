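months,patients
6,3
12,3
24,10
36,4
48,1
72,3
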