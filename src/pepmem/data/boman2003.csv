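residue,value
A,-1.81
C,-1.28
D,8.72
E,6.81
F,-2.98
G,-0.94
H,4.66
I,-4.92
K,5.55
L,-4.92
M,-2.35
N,6.64
P,0.0
Q,5.54
R,14.92
S,3.40
T,2.57
V,-4.04
W,-2.33
Y,0.14
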