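MAPK1
SP1
HDAC1
YY1
ABL1
PTK2
SMAD2
NCOA3
CDC25A
NCOA2
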