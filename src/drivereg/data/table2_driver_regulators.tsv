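TF	E10.5	E11.5	E12.5	E14.5
Foxp2	1	1	1	1
Hmga2	1	1	1	1
Meis1	1	1	1	1
Meox2	1	1	1	1
Tcf7l2	1	1	1	1
Fli1	1	1	1	0
Lef1	0	1	1	1
Prrx1	1	1	0	1
Prrx2	0	1	1	1
Six2	1	1	1	0
Creb3l1	0	1	0	1
Ebf1	1	0	1	0
Ets1	0	1	0	1
Foxp4	1	1	0	0
Hoxb3	0	1	1	0
Klf6	0	1	0	1
Nfatc4	0	1	0	1
Nfib	0	1	1	0
Pax7	0	0	1	1
Pbx1	0	1	0	1
Rreb1	0	0	1	1
Tbx15	1	1	0	0
Tcf4	1	0	1	0
Twist1	1	1	0	0
Zic4	1	0	1	0
Zmiz1	0	1	1	0
Ar	0	0	0	1
Arid5b	0	0	1	0
Atf3	0	0	0	1
Chd2	1	0	0	0
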