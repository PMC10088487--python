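phoneme_label	class
AA	V
AE	V
AH	V
AO	V
AW	V
AY	V
EH	V
ER	V
EY	V
IH	V
IY	V
OW	V
OY	V
UH	V
UW	V
B	P
D	P
G	P
K	P
P	P
T	P
F	F
V	F
S	F
Z	F
SH	F
ZH	F
TH	F
DH	F
HH	F
M	N
N	N
NG	N
L	A
R	A
W	A
Y	A
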