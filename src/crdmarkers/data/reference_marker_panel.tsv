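# Published mouse liver marker panel for chronic circadian rhythm disruption.
# consensus = selected by all three classifier families (classification route);
# blood = passed the sequential filter cascade as potentially blood-detectable.
gene	consensus	blood
Cyp2c29	1	1
Cyp2b10	0	1
Rbp1	1	1
Sult2a1	1	0
Cd36	1	1
Ntrk2	1	1
Tusc3	1	0
Armcx3	1	0
Gspt2	1	0
Snrpn	1	1
Tceal8	1	0
Fkbp11	1	0
Orm2	1	0
Gm3787	1	0
Gm9299	1	0
D630033O11Rik	1	0
Igh-VJ558	0	1
Srgap3	0	1
Tram1	0	1
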