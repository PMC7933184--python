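# van der Waals radii by element, in nm (Bondi 1964 set, with common extensions)
# version: bondi-1964.1
element	vdw_radius_nm
H	0.120
C	0.170
N	0.155
O	0.152
S	0.180
P	0.180
F	0.147
CL	0.175
BR	0.185
I	0.198
NA	0.227
K	0.275
MG	0.173
CA	0.231
ZN	0.139
FE	0.194
SE	0.190
SI	0.210
B	0.192
HE	0.140
NE	0.154
AR	0.188
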