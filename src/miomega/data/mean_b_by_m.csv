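variable,m,B_bar
PRACSIZE2,2,0.053
PRACSIZE2,10,0.108
PRACSIZE2,20,0.116
PRACSIZE2,30,0.107
PRACSIZE2,40,0.120
PRACSIZE2,60,0.131
PRACSIZE2,80,0.107
PRACSIZE2,100,0.101
PRACSIZE5,2,2.39
PRACSIZE5,10,1.03
PRACSIZE5,20,0.98
PRACSIZE5,30,1.08
PRACSIZE5,40,1.03
PRACSIZE5,60,0.86
PRACSIZE5,80,0.96
PRACSIZE5,100,1.02
PRACSIZE20,2,10.2
PRACSIZE20,10,12.8
PRACSIZE20,20,16.8
PRACSIZE20,30,15.4
PRACSIZE20,40,16.2
PRACSIZE20,60,14.1
PRACSIZE20,80,16.6
PRACSIZE20,100,15.6
PRACSIZE100,2,103
PRACSIZE100,10,158
PRACSIZE100,20,168
PRACSIZE100,30,171
PRACSIZE100,40,168
PRACSIZE100,60,184
PRACSIZE100,80,178
PRACSIZE100,100,186
CLSTAFF1,2,100
CLSTAFF1,10,244
CLSTAFF1,20,197
CLSTAFF1,30,200
CLSTAFF1,40,255
CLSTAFF1,60,228
CLSTAFF1,80,238
CLSTAFF1,100,232
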