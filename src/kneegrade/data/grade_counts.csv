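grade,algorithm_vs_expert1,expert1,algorithm_vs_expert2,expert2
Normal,649,651,643,628
Doubtful,530,528,536,551
Mild,279,279,279,279
Moderate,260,260,260,260
Severe,282,282,282,282
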