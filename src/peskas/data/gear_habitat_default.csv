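gear,reef,FAD,deep,shore,mangrove
gill net,1,0,0,1,1
seine net,1,0,0,1,0
beach seine,0,0,0,1,0
hand line,1,1,1,0,0
long line,0,1,1,0,0
spearfishing,1,0,0,1,0
trap,1,0,0,1,1
gleaning,1,0,0,1,1
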