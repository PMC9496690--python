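sample_id,cohort,label,score
A,non_fad,normal,91.85
F,non_fad,normal,85.94
G,non_fad,normal,84.09
H,non_fad,normal,92.86
I,non_fad,normal,80.22
M,non_fad,normal,90.91
X,non_fad,normal,87.5
AA,non_fad,normal,100
B,non_fad,dementia,54.55
N,non_fad,dementia,88.64
O,non_fad,dementia,86.11
R,non_fad,dementia,31.25
S,non_fad,dementia,100
U,non_fad,dementia,89.80
W,non_fad,dementia,57.81
Y,non_fad,dementia,65.08
AB,non_fad,dementia,75
D,fad,fad_pos,49
E,fad,fad_pos,100
K,fad,fad_neg,85
L,fad,fad_neg,100
P,fad,fad_neg,85
Q,fad,fad_pos,53
Z,fad,fad_pos,100
AC,fad,fad_pos,98
AD,fad,fad_neg,95
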