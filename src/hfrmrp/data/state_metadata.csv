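state_code,has_urban_county
AK,0
AL,1
AR,1
AZ,1
CA,1
CO,1
CT,1
DE,1
FL,1
GA,1
HI,1
IA,1
ID,1
IL,1
IN,1
KS,1
KY,1
LA,1
MA,1
MD,1
ME,0
MI,1
MN,1
MO,1
MS,1
MT,0
NC,1
ND,0
NE,1
NH,1
NJ,1
NM,1
NV,1
NY,1
OH,1
OK,1
OR,1
PA,1
RI,1
SC,1
SD,0
TN,1
TX,1
UT,1
VA,1
VT,0
WA,1
WI,1
WV,1
WY,0
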