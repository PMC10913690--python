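zone,side,x,y
B,upper,0,50
B,upper,30,50
B,upper,140,170
B,upper,280,380
B,upper,430,550
C,upper,0,60
C,upper,30,60
C,upper,50,80
C,upper,70,110
C,upper,260,550
D,upper,0,100
D,upper,25,100
D,upper,50,125
D,upper,80,215
D,upper,125,550
E,upper,0,150
E,upper,35,155
E,upper,50,550
B,lower,50,0
B,lower,50,30
B,lower,170,145
B,lower,385,300
B,lower,550,450
C,lower,120,0
C,lower,120,30
C,lower,260,130
C,lower,550,250
D,lower,250,0
D,lower,250,40
D,lower,550,150
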