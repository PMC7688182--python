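speaker,measure,adaptation,mARE,MRE,r,n_children
adult,TNU,raw,55.7143,-55.7143,0.9987,2
adult,TNU,adapted,55.7143,-55.7143,0.9987,2
adult,TNW,raw,66.8067,-66.8067,0.999,2
adult,TNW,adapted,66.8067,-66.8067,0.999,2
adult,NDW,raw,62.5,-62.5,0.9975,2
adult,NDW,adapted,62.5,-62.5,0.9975,2
adult,MLU,raw,25.0474,-25.0474,,1
adult,MLU,adapted,25.0474,-25.0474,,1
adult,TTR,raw,12.9747,12.9747,,1
adult,TTR,adapted,12.9747,12.9747,,1
peer,TNU,raw,12.5,-12.5,0.9592,3
peer,TNU,adapted,12.5,-12.5,0.9592,3
peer,TNW,raw,32.3529,-32.3882,1.0,3
peer,TNW,adapted,32.3529,-32.3882,1.0,3
peer,NDW,raw,32.2581,-29.5561,0.9907,3
peer,NDW,adapted,32.2581,-29.5561,0.9907,3
peer,MLU,raw,24.6201,-21.5551,0.803,3
peer,MLU,adapted,24.6201,-21.5551,0.803,3
peer,TTR,raw,3.7037,4.354,0.8525,3
peer,TTR,adapted,3.7037,4.354,0.8525,3
focal,TNU,raw,12.5,-37.5,0.9934,3
focal,TNU,adapted,12.5,-37.5,0.9934,3
focal,TNW,raw,26.3158,-49.0018,0.9997,3
focal,TNW,adapted,26.3158,-49.0018,0.9997,3
focal,NDW,raw,23.5294,-47.5867,1.0,3
focal,NDW,adapted,23.5294,-47.5867,1.0,3
focal,MLU,raw,18.2396,-18.2396,1.0,2
focal,MLU,adapted,18.2396,-18.2396,1.0,2
focal,TTR,raw,2.8105,2.8105,-1.0,2
focal,TTR,adapted,2.8105,2.8105,-1.0,2
adult,TDI,raw,63.2194,-63.2194,0.9996,2
adult,TDI,adapted,63.2194,-63.2194,0.9996,2
peer,TDI,raw,5.9016,-7.5352,1.0,3
peer,TDI,adapted,5.9016,-7.5352,1.0,3
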