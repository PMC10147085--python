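alternative,Specificity,Target binding affinity,Brain uptake and penetration,Adverse reactions
aim,max,max,max,min
weight,VH,H,VH,M
[18F]AV-1451,VH,L,H,M
[11C]PBB3,H,M,H,M
[18F]THK5105,M,L,M,M
[18F]THK5117,M,L,M,M
[18F]THK5317,M,L,M,L
[18F]THK5351,H,L,M,L
[18F]MK-6240,H,VH,VH,L
[18F]GTP1,H,H,H,M
[18F]PM-PBB3,H,H,H,L
[18F]JNJ-067,H,VH,H,L
[18F]JNJ-311,H,H,H,L
[11C]RO-643,VH,VH,VH,M
[11C]RO-963,VH,VH,VH,M
[18F]RO-948,VH,VH,VH,L
[18F]PI-2620,H,VH,H,M
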