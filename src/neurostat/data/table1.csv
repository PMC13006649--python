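batch,IT,IA,SSH,response
#5,10,0.1,15/10,6.08e8
#6,15,0.1,30/25,5.71e8
#7,20,0.1,50/45,6.36e8
#8,15,0.3,15/10,4.92e8
#9,20,0.3,30/25,5.89e8
#10,10,0.3,50/45,7.52e8
#11,20,0.5,15/10,5.60e8
#12,10,0.5,30/25,6.30e8
#13,15,0.5,50/45,7.04e8
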