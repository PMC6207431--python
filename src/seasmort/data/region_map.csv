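state,region
IL,central
IN,central
KY,central
MO,central
OH,central
TN,central
WV,central
IA,east_north_central
MI,east_north_central
MN,east_north_central
WI,east_north_central
CT,northeast
DC,northeast
DE,northeast
MA,northeast
MD,northeast
ME,northeast
NH,northeast
NJ,northeast
NY,northeast
PA,northeast
RI,northeast
VT,northeast
AK,northwest
ID,northwest
OR,northwest
WA,northwest
AR,south
KS,south
LA,south
MS,south
OK,south
TX,south
AL,southeast
FL,southeast
GA,southeast
NC,southeast
SC,southeast
VA,southeast
AZ,southwest
CO,southwest
NM,southwest
UT,southwest
CA,west
HI,west
NV,west
MT,west_north_central
ND,west_north_central
NE,west_north_central
SD,west_north_central
WY,west_north_central
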