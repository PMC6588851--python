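ensemble_id,hijab,top,bottom,socks,exposed_segments,exposed_percentage
long-long,False,long,long,False,head-and-neck;hand;hand;foot;foot,18
short-short,False,short,short,False,head-and-neck;arm-exposed-short-sleeve;arm-exposed-short-sleeve;leg-exposed-short-bottom;leg-exposed-short-bottom,48
short-long,False,short,long,False,head-and-neck;arm-exposed-short-sleeve;arm-exposed-short-sleeve;foot;foot,25
hijab,True,long,long,False,face;hand;hand;foot;foot,13.5
hijab-socks,True,long,long,True,face-tight-hijab;hand;hand,8
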