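well,set_id,dilution_step,concentration
A1,A1-6,0,
A2,A1-6,1,
A3,A1-6,2,
A4,A1-6,3,
A5,A1-6,4,
A6,A1-6,5,
A7,A7-12,0,
A8,A7-12,1,
A9,A7-12,2,
A10,A7-12,3,
A11,A7-12,4,
A12,A7-12,5,
B1,B1-6,0,
B2,B1-6,1,
B3,B1-6,2,
B4,B1-6,3,
B5,B1-6,4,
B6,B1-6,5,
B7,B7-12,0,
B8,B7-12,1,
B9,B7-12,2,
B10,B7-12,3,
B11,B7-12,4,
B12,B7-12,5,
C1,C1-6,0,
C2,C1-6,1,
C3,C1-6,2,
C4,C1-6,3,
C5,C1-6,4,
C6,C1-6,5,
C7,C7-12,0,
C8,C7-12,1,
C9,C7-12,2,
C10,C7-12,3,
C11,C7-12,4,
C12,C7-12,5,
D1,D1-6,0,
D2,D1-6,1,
D3,D1-6,2,
D4,D1-6,3,
D5,D1-6,4,
D6,D1-6,5,
D7,D7-12,0,
D8,D7-12,1,
D9,D7-12,2,
D10,D7-12,3,
D11,D7-12,4,
D12,D7-12,5,
E1,E1-6,0,
E2,E1-6,1,
E3,E1-6,2,
E4,E1-6,3,
E5,E1-6,4,
E6,E1-6,5,
E7,E7-12,0,
E8,E7-12,1,
E9,E7-12,2,
E10,E7-12,3,
E11,E7-12,4,
E12,E7-12,5,
F1,F1-6,0,
F2,F1-6,1,
F3,F1-6,2,
F4,F1-6,3,
F5,F1-6,4,
F6,F1-6,5,
F7,F7-12,0,
F8,F7-12,1,
F9,F7-12,2,
F10,F7-12,3,
F11,F7-12,4,
F12,F7-12,5,
G1,G1-6,0,
G2,G1-6,1,
G3,G1-6,2,
G4,G1-6,3,
G5,G1-6,4,
G6,G1-6,5,
G7,G7-12,0,
G8,G7-12,1,
G9,G7-12,2,
G10,G7-12,3,
G11,G7-12,4,
G12,G7-12,5,
H1,H1-6,0,
H2,H1-6,1,
H3,H1-6,2,
H4,H1-6,3,
H5,H1-6,4,
H6,H1-6,5,
H7,H7-12,0,
H8,H7-12,1,
H9,H7-12,2,
H10,H7-12,3,
H11,H7-12,4,
H12,H7-12,5,
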