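# Serum lipid reference panel (reconstruction): reproduces the
# published 218-species per-subclass composition; individually
# reported species appear verbatim, remaining names are generated.
DG(34:1)
DG(36:2)
TG(44:0)
TG(46:0)
TG(48:0)
TG(50:0)
TG(52:0)
TG(54:0)
TG(56:0)
TG(58:0)
TG(60:0)
TG(44:1)
TG(46:1)
TG(48:1)
TG(50:1)
TG(52:1)
TG(54:1)
TG(56:1)
TG(58:1)
TG(60:1)
TG(44:2)
TG(46:2)
TG(48:2)
TG(50:2)
TG(52:2)
TG(54:2)
TG(56:2)
TG(58:2)
TG(60:2)
TG(44:3)
TG(46:3)
TG(48:3)
TG(50:3)
TG(52:3)
TG(54:3)
TG(56:3)
TG(58:3)
TG(60:3)
TG(44:4)
TG(46:4)
TG(48:4)
TG(50:4)
TG(52:4)
TG(54:4)
TG(56:4)
TG(58:4)
TG(60:4)
TG(44:5)
TG(46:5)
TG(48:5)
TG(50:5)
TG(52:5)
TG(54:5)
TG(56:5)
TG(58:5)
TG(60:5)
TG(44:6)
TG(46:6)
TG(48:6)
TG(50:6)
CE(22:6)
CE(20:5)
CE(16:0)
CE(16:1)
CE(18:0)
PC(16:0_18:0)
PC(16:0_16:1)
PC(16:0/22:5)
PC(16:0/16:0)
PC(36:6)
PC(16:0_16:0)
PC(16:0_18:1)
PC(16:0_18:2)
PC(16:0_18:3)
PC(16:0_20:3)
PC(16:0_20:4)
PC(16:0_20:5)
PC(16:0_22:5)
PC(16:0_22:6)
PC(16:0_14:0)
PC(16:1_16:1)
PC(16:1_18:0)
PC(16:1_18:1)
PC(16:1_18:2)
PC(16:1_18:3)
PC(16:1_20:3)
PC(16:1_20:4)
PC(16:1_20:5)
PC(16:1_22:5)
PC(16:1_22:6)
PC(16:1_14:0)
PC(18:0_18:0)
PC(18:0_18:1)
PC(18:0_18:2)
PC(18:0_18:3)
PC(18:0_20:3)
PC(18:0_20:4)
PC(18:0_20:5)
PC(18:0_22:5)
PC(18:0_22:6)
PC(18:0_14:0)
PC(18:1_18:1)
PC(18:1_18:2)
PC(18:1_18:3)
PC(18:1_20:3)
PC(18:1_20:4)
PC(18:1_20:5)
PC(O-34:2)
PC(O-30:0)
PC(O-32:0)
PC(O-34:0)
PC(O-36:0)
PC(O-38:0)
PC(O-40:0)
PC(O-30:1)
PC(O-32:1)
PC(O-34:1)
PC(O-36:1)
PC(O-38:1)
PC(O-40:1)
PC(O-30:2)
PC(O-32:2)
PC(O-36:2)
LPC(16:0)
LPC(18:2)
LPC(16:1)
LPC(18:0)
LPC(18:1)
LPC(18:3)
LPC(20:3)
LPC(20:4)
LPC(20:5)
LPC(22:5)
LPC(22:6)
LPC(14:0)
LPC(15:0)
LPC(17:0)
LPC(17:1)
PI(18:0/20:4)
PI(34:1)
PI(36:2)
PI(36:4)
PI(34:2)
PI(16:0_16:0)
PI(16:0_16:1)
LPI(16:0)
LPI(16:1)
PE(16:0_22:6)
PE(16:0_16:0)
PE(16:0_16:1)
PE(16:0_18:0)
PE(16:0_18:1)
PE(16:0_18:2)
PE(16:0_18:3)
PE(16:0_20:3)
PE(16:0_20:4)
PE(16:0_20:5)
PE(16:0_22:5)
PE(O-30:0)
PE(O-32:0)
PE(O-34:0)
PE(O-36:0)
PE(O-38:0)
PE(O-40:0)
PE(O-30:1)
PE(O-32:1)
PE(O-34:1)
PE(O-36:1)
PE(O-38:1)
PE(O-40:1)
PE(O-30:2)
PE(O-32:2)
PE(O-34:2)
PE(P-34:1)
LPE(16:0)
LPE(16:1)
LPE(18:0)
LPE(18:1)
LPE(18:2)
LPE(18:3)
LPE(20:3)
LPE(O-16:0)
LPE(O-18:0)
Cer(18:1;2/24:0)
Cer(18:2;2/24:0)
Cer(18:1;2/16:0)
Cer(18:1;2/24:1)
Cer(18:1;2/18:0)
Cer(18:1;2/20:0)
SM(37:2;3)
SM(18:1;2/24:0)
SM(32:2;2)
SM(38:2;2)
SM(32:1;2)
SM(33:1;2)
SM(34:1;2)
SM(35:1;2)
SM(36:1;2)
SM(37:1;2)
SM(38:1;2)
SM(39:1;2)
SM(40:1;2)
SM(41:1;2)
SM(42:1;2)
SM(43:1;2)
SM(33:2;2)
SM(34:2;2)
SM(35:2;2)
SM(36:2;2)
SM(37:2;2)
SM(39:2;2)
SM(40:2;2)
SM(41:2;2)
Hex1Cer(18:1;2/16:0)
Hex1Cer(18:1;2/22:0)
Hex1Cer(18:1;2/24:0)
Hex1Cer(18:1;2/24:1)
Hex2Cer(18:1;2/16:0)
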