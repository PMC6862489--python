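marker,chromosome,position_mb
J521,2,7.6
RM3390,2,7.7
J527,2,8.2
J529,2,8.6
J536,2,9.1
RM6375,2,9.6
RM1358,2,10.2
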