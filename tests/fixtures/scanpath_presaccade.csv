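subject,trial,fixation_index,word_index,region_id,landing_char,onset_ms,duration_ms
1,1,0,0,0,2.0,0,200
1,1,1,1,0,8.0,200,160
1,1,2,2,1,14.0,360,120
1,1,3,1,0,8.5,480,180
1,1,4,2,1,14.5,660,240
1,1,5,3,1,20.0,900,140
2,1,0,0,0,2.0,0,220
2,1,1,1,0,8.0,220,180
2,1,2,2,1,14.0,400,160
2,1,3,3,1,20.0,560,100
2,1,4,1,0,8.0,660,260
2,1,5,3,1,20.5,920,150
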