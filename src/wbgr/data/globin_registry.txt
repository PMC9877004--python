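HBA1
HBA2
HBB
HBD
HBE1
HBG1
HBG2
HBM
HBQ1
HBZ
HBAP1
HBBP1
HBZP1
HBDP1
HBGP1
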