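subject,trial,fixation_index,word_index,region_id,landing_char,onset_ms,duration_ms
1,1,0,0,0,2.0,0,150
1,1,1,2,2,14.0,150,180
1,1,2,3,3,20.0,330,200
1,1,3,1,1,8.0,530,250
1,1,4,3,3,21.0,780,130
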