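aoi,video_id,r1_pct,r2_pct
rice,A,28.8,32.2
meatballs,A,7.3,14
vegetables,A,14.3,14.9
mixed,A,15.1,10
border,A,5.4,2.1
empty,A,21.4,19.3
bread,A,7.8,7.5
rice,B,28.7,29.3
meatballs,B,11.8,9.6
vegetables,B,13.7,18.2
mixed,B,10.1,8
border,B,3.7,4.6
empty,B,19.5,18.9
bread,B,12.5,11.3
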