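predicted,Normal,Doubtful,Mild,Moderate,Severe
Normal,622,21,0,0,0
Doubtful,6,530,0,0,0
Mild,0,0,279,0,0
Moderate,0,0,0,260,0
Severe,0,0,0,0,282
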