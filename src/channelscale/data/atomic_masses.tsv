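# Standard atomic masses (Da), element-keyed.
element	mass
H	1.008
C	12.011
N	14.007
O	15.999
S	32.06
P	30.974
F	18.998
CL	35.45
BR	79.904
I	126.904
NA	22.990
K	39.098
MG	24.305
CA	40.078
ZN	65.38
FE	55.845
SE	78.971
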