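marker,direction
BrdU,-1
F-actin,-1
dPsim,-1
caspase3,1
collagenIII,-1
MMP-2,1
TIMP-1,-1
DHE,-1
Smad3,-1
pCREB,-1
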