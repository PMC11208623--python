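prefix	region
A	Americas
B	Americas
C	Americas
D	Americas
X	Americas
L	Africa
H	Europe
V	Europe
J	Europe
T	Europe
U	Europe
K	Europe
I	Europe
W	Europe
M	Asia
N	Asia
R	Asia
F	Asia
G	Asia
Y	Asia
Z	Asia
P	Oceania
Q	Oceania
S	Oceania
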