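weight,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,S11
W1,30,50,30,45,30,20,60,30,25,50,30
W2,30,20,30,45,30,50,30,30,10,20,10
W3,20,10,20,10,20,20,10,20,25,20,40
W4,20,20,20,0,20,10,0,20,40,10,20
a1,10,15,5,5,5,20,30,5,5,5,25
a2,50,40,35,30,45,20,30,60,45,45,25
a3,0,15,35,35,20,20,30,5,25,5,25
a4,40,30,25,30,30,40,10,30,25,45,25
b1,60,50,50,50,50,80,50,40,50,100,30
b2,40,50,50,50,50,20,50,60,50,0,70
c1,10,10,5,5,5,20,17,0,10,5,10
c2,30,30,25,25,40,40,17,30,30,40,35
c3,5,10,25,25,40,10,16,10,10,5,15
c4,25,10,15,15,5,10,17,0,10,5,10
c5,25,30,15,15,5,10,17,30,30,40,15
c6,5,10,15,15,5,10,16,30,10,5,15
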