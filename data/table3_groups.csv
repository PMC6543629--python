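set_id,group,expected_fold
A1-6,100ng,1
A7-12,100ng,1
B1-6,100ng,1
B7-12,100ng,1
C1-6,50ng,2
C7-12,50ng,2
D1-6,50ng,2
D7-12,50ng,2
E1-6,12ng,8
E7-12,12ng,8
F1-6,12ng,8
F7-12,12ng,8
G1-6,3ng,32
G7-12,3ng,32
H1-6,3ng,32
H7-12,3ng,32
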