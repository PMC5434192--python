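index,name,x,y,z,surface_area,network
1,L dorsolateral prefrontal cortex,-36.6,20.2,23.9,747.3,default
2,R dorsolateral prefrontal cortex,35.1,8.3,33.7,470.4,default
3,L subcentral gyrus,-48.1,-10.2,10.3,590.6,somatomotor
4,R dorsal prefrontal cortex,26.2,35.1,33.0,1601.9,default
5,L anterior medial prefrontal cortex,-9.7,45.7,7.8,987.7,default
6,R anterior medial prefrontal cortex,9.1,50.6,7.3,1052.8,default
7,L precentral gyrus,-20.6,-22.3,72.5,622.0,somatomotor
8,R postcentral gyrus,28.0,-35.5,62.6,1169.9,somatomotor
9,R middle temporal complex,47.7,-66.6,-11.8,596.4,visual
10,L lingual gyrus,-17.9,-63.1,-6.1,618.4,visual
11,R anterior prefrontal cortex,8.2,61.2,25.6,564.2,default
12,R occipito-parietal lobe,15.9,-92.7,18.8,783.9,visual
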