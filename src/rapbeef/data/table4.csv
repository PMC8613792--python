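indicator,entity,actual,printed_score,consistent
PE1,Semarang,143.09,1,True
PE1,Boyolali,1657.29,1,True
PE1,Sragen,2174.84,1,False
PE2,Semarang,2.43,1,True
PE2,Boyolali,2.35,1,True
PE2,Sragen,0.93,1,True
PE3,Semarang,170.28,6,True
PE3,Boyolali,519.11,6,True
PE3,Sragen,88.70,5,True
PE4,Semarang,1.67,1,True
PE4,Boyolali,0.96,1,True
PE4,Sragen,0.17,1,True
PS1,Semarang,1.094,2,True
PS1,Boyolali,1.039,2,True
PS1,Sragen,1.436,2,False
PS2,Semarang,53.12,3,False
PS2,Boyolali,46.72,3,False
PS2,Sragen,48.62,3,False
PS3,Semarang,19.13,3,False
PS3,Boyolali,24.89,3,False
PS3,Sragen,25.00,3,False
PS4,Semarang,6.07,6,True
PS4,Boyolali,1.41,6,True
PS4,Sragen,1.57,6,True
PL1,Semarang,520662.86,5,False
PL1,Boyolali,925988.57,2,True
PL1,Sragen,436699.21,5,True
PL2,Semarang,1668.25,5,True
PL2,Boyolali,3157.93,4,True
PL2,Sragen,4877.75,2,True
PL3,Semarang,846.30,5,True
PL3,Boyolali,1913.94,2,True
PL3,Sragen,1300.83,4,True
RE1,Semarang,3215.13,1,True
RE1,Boyolali,23342.99,2,True
RE1,Sragen,12288.95,1,True
RE2,Semarang,170.28,6,True
RE2,Boyolali,519.11,6,True
RE2,Sragen,88.70,5,True
RS1,Semarang,10.75,4,True
RS1,Boyolali,17,6,True
RS1,Sragen,5,2,True
RS2,Semarang,27.91,2,False
RS2,Boyolali,23.53,2,False
RS2,Sragen,100.00,6,True
RS3,Semarang,4.65,1,True
RS3,Boyolali,0.00,1,True
RS3,Sragen,0.00,1,True
RS4,Semarang,1.94,1,False
RS4,Boyolali,0.13,1,False
RS4,Sragen,7.88,1,False
RL1,Semarang,367.86,2,True
RL1,Boyolali,142.86,5,True
RL1,Sragen,180.00,5,True
RL2,Semarang,362.86,2,True
RL2,Boyolali,142.86,5,True
RL2,Sragen,100.29,5,True
RL3,Semarang,846.30,5,True
RL3,Boyolali,1913.94,2,True
RL3,Sragen,1300.83,4,True
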