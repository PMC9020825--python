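E10.5 Anterior somites	E11.5 EOM Myogenic	E11.5 EOM Non-myogenic	E12.5 Non-myogenic	E14.5 Non-myogenic
Tshz2	Ccdc141	Zfpm2	Mgat4c	Dnm1
Eya1	Mcm6	Plxna4	Cenpv	Pid1
C1qtnf3	Dync1i1	Col23a1	C130073E24Rik	Nrp2
Meis2	Tpm2	Edil3	Tbx3os1	Ntrk3
Limch1	Celf2	Map2	E330013P04Rik	Tmem132c
Moxd1	Sox6	Rora	Stk26	Egflam
Epha4	Tnc	Sema5a	Edil3	Gpr153
Pitx2	Magi3	Colec12	Fdft1	Efemp1
Parm1	Sh3glb1	Smoc1	Lima1	Adamts2
Hpse2	Parm1	Ptprt	Trim59	Brinp1
Lrrn1	Ephb1	Ror1	Meg3	Vegfc
Dmrt2	Bmpr1b	Dock5	Gins3	Twist2
Myl3	Hells	Map1b	Tpm2	Itgb5
Fap	Pdgfc	Fn1	Cdh6	Gria1
Hs6st2	Ptprd	Limch1	Csmd3	Sned1
Ddr2	Cnr1	Tenm4	Tceal5	Sorcs3
Cald1	Sema3d	Rbms3	Pclaf	Ebf2
Prrx1	Clcn5	Srgap3	Tspan9	Fam19a1
Magi3	Chd7	Tmem132c	Eps8	Trabd2b
Ntn1	Col25a1	Sdc2	Lmna	Plxdc2
Zfhx3	Reep1	Add3	Dmrt2	Sh3gl3
Meis1	Ctnnal1	Pdgfra	Cpeb4	Luzp2
Tnni1	Tpm1	Gmds	Hpgd	Pdzd2
Crym	Zim1	St6galnac3	Rcsd1	Sema3e
Ebf1	Lmx1a	Epb41l3	Pdgfra	Rims1
Nr2f1	Neb	Pde3a	Plac1	Epha3
Ntng1	Atad2	Tox	Palmd	Cyp7b1
Pgm5	Dapk2	Smarca2	Gucy1a1	Gem
Cdh6	Prox1	Ctdspl	Wif1	Ldb2
Foxp1	Lsamp	Magi2	Naalad2	Scube1
Celf2	Ttn	Dpysl3	Smoc2	Pdgfra
Tbx1	Pls3	Fgfr2	Rassf4	Pde1a
Bdnf	Slf2	Ldb2	Pttg1	Nde1
Colec12	Vat1l	Igf1	Josd2	Enpp2
Eya4	E2f1	Elk3	Plxna4	Fam107b
Sobp	Epb41l2	Zmiz1	Eya2	Stxbp6
Peg3	Gm28653	Dlc1	Nrsn1	Rerg
Pdgfra	Lrrn1	Nhs	Fign	Prex2
Nrk	Mef2c	Cdkn1c	Inppl1	Man1a
Ptn	St8sia2	Plpp3	Rnf152	Tmem45a
Daam1	Tshz1	Ebf1	Lasp1	Sh3bp4
Dlk1	Wee1	Sorbs2	Mrln	Mcc
Unc5c	Slc24a3	Baz1a	Cdt1	Ncald
Lpar1	Ncoa1	Fat4	Notch3	Kdelr2
Syne2	Dek	Golgb1	Pax3	Pcdh19
Nkd2	Kdm5b	Hpse2	Egfr	Gas7
Brinp1	Unc13c	Samd4	Dbf4	Cpt1c
Zfhx4	Ddr1	Itga9	Bcr	Adam22
Nnat	Pip4k2a	Magi1	Mllt3	Itgb8
Gxylt2	Fndc3c1	Pcdh9	Nectin1	Dchs2
Clmp	Rbm24	Tgfbr2	Grin3a	Cep350
Ror2	Rreb1	Ntf3	Cbfa2t3	Oat
Nfia	Rragd	Col11a1	Cdh2	Rab30
Ebf2	Acsl3	Runx1t1	Anln	Aff2
Ednra	Acvr2a	Tnrc18	Ccdc6	Gna14
Fli1	Zeb1	Crym	Mcu	Slc29a1
Tspan12	Rgma	Fap	Fnip2	Pls3
Ttc28	Arpp21	Ppp1r1a	Kcnk13	Traf3ip1
Nfib	Lef1	Tes	Sned1	Rcsd1
Ccdc88c	Nr2f2	Bicc1	Nde1	Lgr4
Col13a1	Foxo1	Il1rapl1	Hipk3	Zfp9
2700069I18Rik	Pdzrn4	Alcam	Arhgap11a	Hs3st5
Pcolce	Hmga2	2700069I18Rik	Fam8a1	Aspn
Scn3a	Lurap1l	Dab2	Kif21a	Nrxn1
Acvr2a	Pkig	Cntln	Mtss1	Rrm1
Auts2	Ncl	Clmn	Abcd2	Igfbp7
Col3a1	CT025619.1	Rbms1	Irx5	Slc35f3
Gap43	Erbb4	Tmem2	Pacs2	Kif15
Mrln	Cdk14	Cdh6	Nab1	Slc1a3
Pax3	Kif21a	Lypd6	Ccnd2	Bmp6
Sim1	Zfp704	Mmp2	Bok	Dkk2
Epb41l2	Nasp	Kif5c	Dok5	Tspan9
Ppp3ca	Plekha5	Cadm2	Ncapg	Ets1
Tnfaip6	Cap2	Prkg2	Rfx8	Gria3
Tmem132c	Snca	Cped1	Fhod3	Sox8
Tmem2	Epha4	Dtl	Tk1	Melk
Epb41l3	Atad5	Ror2	Asf1b	Ntm
Crybg3	Cntn3	Utrn	Tek	Synpo2l
Nrxn1	Cacna2d1	Foxp1	Arfgef3	Hlf
Farp1	Pak3	L3mbtl3	Rnf182	Adamts5
Sulf1	Megf10	Cdh23	Kif14	Plcb4
Tmtc2	Tnnt1	Negr1	1810041L15Rik	Cdc25b
Pde4dip	Acta2	Hmcn1	Rrm2	Mgat4a
Phldb2	Barx2	Col26a1	Fgf5	Mdfic
Plpp3	Mrln	Fbn2	Barx2	Trpc5
Ybx3	Pgm5	Ankrd12	Fli1	Kif4
Ppm1l	Fmr1	Lhfp	Jph2	Plce1
Twist2	Smc4	Hs3st3b1	Dtx4	Il17rd
Nuak1	Clmp	Adgrl3	Ncald	Mmp16
Tgfb2	Alpk2	Svil	Zic4	Hhip
Sfrp1	Kctd1	Mob3b	Dlc1	Tpx2
Sncaip	Meg3	Trabd2b	Cdc45	Ndc80
Tenm3	Samd5	Rmst	Gatm	Bub1b
Cdh2	Nrk	Prrx1	Ssc5d	Hmmr
Iqgap2	Piezo2	5330434G04Rik	Phactr2	Kank4
App	Robo1	Zfhx3	Ppp1r14c	Tmeff2
Pgam2	Col1a2	Foxp2	Agl	Nr4a1
Rspo3	Cntrl	Mpp6	Tox3	Aurkb
Cdon	Mllt3	Crispld1	Aurka	Lrrtm3
Ebf3	Peg3	Eya1	Cdh15	Cenpq
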