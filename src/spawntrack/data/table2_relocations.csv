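year,zone_1,zone_2,zone_3,zone_4,zone_5,zone_6,zone_7
2007,11,505,622,662,15,28,883
2008,0,304,448,321,1,4,289
2009,0,267,432,123,8,1,419
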