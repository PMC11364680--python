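stratum,green,yellow,red
non_cancer,1928,2616,349
screen_detected,1,10,57
interval,2,12,15
missed,2,2,4
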