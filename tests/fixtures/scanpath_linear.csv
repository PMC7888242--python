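subject,trial,fixation_index,word_index,region_id,landing_char,onset_ms,duration_ms
1,1,0,0,0,2.0,0,200
1,1,1,1,1,8.0,200,150
1,1,2,1,1,9.0,350,120
1,1,3,2,2,14.0,470,180
1,1,4,3,3,20.0,650,140
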