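# Miniature synthetic list of mouse transcription-factor symbols used as a
# fixture for TF subsetting.  Real analyses should substitute a genome-wide
# TF catalog (one symbol per line).
Onecut1
Onecut2
Onecut3
Pou2f2
Pou4f1
Zfhx2
Zfhx3
Zfhx4
Nfia
Nfib
Nfix
Neurod2
Neurod6
Tcf4
Sox2
Sox9
Pax3
Pax6
Lhx1
Lhx5
Lhx6
Phox2b
Lmx1a
Lmx1b
Pitx3
Nkx2-2
Sim1
Lbx1
Hes1
Hes5
Zbtb20
Npas3
Meis1
Meis2
Pbx3
Tshz2
Barhl2
Foxg1
Otx2
Gata2
Gata3
Isl1
Ebf1
Hopx
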