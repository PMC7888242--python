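subject,trial,fixation_index,word_index,region_id,landing_char,onset_ms,duration_ms
1,1,0,8,3,42.0,0,180
1,1,1,7,3,37.0,180,150
1,1,2,9,4,47.0,330,160
1,1,3,5,2,27.0,490,170
1,1,4,9,4,47.0,660,140
1,1,5,7,3,37.0,800,155
1,1,6,9,4,47.0,955,150
1,1,7,3,1,17.0,1105,165
1,1,8,9,4,47.0,1270,145
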