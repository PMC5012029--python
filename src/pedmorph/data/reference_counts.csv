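model,scheme,morph,expected,observed
model2,equal,O,18,21
model2,equal,Y,21,13
model2,equal,OY,14.63,12
model2,equal,G,4.38,12
model2,hwe,O,16.7,21
model2,hwe,Y,23.2,13
model2,hwe,OY,13.32,12
model2,hwe,G,4.76,12
model2,threshold,O,17.25,21
model2,threshold,Y,19.75,13
model2,threshold,OY,15.25,12
model2,threshold,G,5.75,12
model3,equal,O,13.38,21
model3,equal,Y,15.63,13
model3,equal,OY,15.13,12
model3,equal,G,13.88,12
model3,hwe,O,12.31,21
model3,hwe,Y,14.83,13
model3,hwe,OY,21.35,12
model3,hwe,G,9.51,12
model3,threshold,O,11,21
model3,threshold,Y,13.5,13
model3,threshold,OY,23.5,12
model3,threshold,G,10,12
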