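# Van der Waals radii (Å), Bondi-type element values.
element	vdw_radius
H	1.20
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
F	1.47
CL	1.75
BR	1.85
I	1.98
NA	2.27
K	2.75
MG	1.73
CA	2.31
ZN	1.39
FE	1.52
SE	1.90
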