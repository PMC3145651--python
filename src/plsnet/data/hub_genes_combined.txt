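SP1
JUN
FOS
ESR1
JUNB
HDAC1
EGFR
YY1
PTK2
MAPK1
ABL1
CDH1
SMAD2
NCOA3
SOCS3
HGF
GRB2
IGF1
NCOA2
ETS2
ATF3
CDC25A
SERPINE1
DUSP1
ID2
MAPT
SREBF1
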