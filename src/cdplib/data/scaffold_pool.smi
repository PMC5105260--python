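c1ccccc1
c1ccncc1
c1ccnnc1
c1cncnc1
c1cnccn1
c1cc[nH]c1
c1ccoc1
c1ccsc1
c1c[nH]cn1
c1cn[nH]c1
c1cocn1
c1cscn1
c1nnc[nH]1
c1cn[nH]n1
c1nnn[nH]1
c1ccc2ccccc2c1
c1ccc2ncccc2c1
c1ccc2cnccc2c1
c1ccc2[nH]ccc2c1
c1ccc2occc2c1
c1ccc2sccc2c1
c1ccc2[nH]cnc2c1
c1ccc2n[nH]cc2c1
c1ncc2[nH]cnc2n1
c1ccc2ncncc2c1
c1ccc2nccnc2c1
c1ccc2nnccc2c1
c1cnc2nccnc2n1
c1ccc2c(c1)[nH]c1ccccc12
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CCCCCC1
C1CCCCCCC1
C1=CCCCC1
C1=CCCC1
C1CCNC1
C1CCNCC1
C1CNCCN1
C1COCCN1
C1CSCCN1
C1CCOC1
C1CCOCC1
C1COCCO1
C1CCSC1
C1CCSCC1
C1CNC1
C1COC1
C1CN1
C1CO1
C1CCC2CCCCC2C1
c1ccc2c(c1)CCC2
c1ccc2c(c1)CCCC2
c1ccc2c(c1)OCO2
c1ccc2c(c1)CCO2
c1ccc2c(c1)CCN2
c1ccc2c(c1)OCCO2
c1ccc2c(c1)CCNC2
C1CC2CCC1CC2
c1ccc(-c2ccccc2)cc1
c1ccc(-c2ccncc2)cc1
c1ccc(-c2cccnc2)cc1
c1ccc(-c2ncccn2)cc1
c1ccc(-c2ccco2)cc1
c1ccc(-c2cccs2)cc1
c1ccc(-c2cc[nH]c2)cc1
c1ccc(Cc2ccccc2)cc1
c1ccc(Oc2ccccc2)cc1
c1ccc(Nc2ccccc2)cc1
c1ccc(Sc2ccccc2)cc1
c1ccc(CCc2ccccc2)cc1
C(=Cc1ccccc1)c1ccccc1
c1ccc(COc2ccccc2)cc1
c1ccc(CNc2ccccc2)cc1
c1ccc(-c2ccc3ccccc3c2)cc1
C1CCC(C2CCCCC2)CC1
C1CCC(CC2CCCCC2)CC1
c1ccc(C2CCCCC2)cc1
c1ccc(CC2CCCCC2)cc1
c1ccc(N2CCNCC2)cc1
c1ccc(N2CCOCC2)cc1
c1ccc(C2CCNCC2)cc1
c1ccc(CN2CCCCC2)cc1
c1ccc(CC2CCNCC2)cc1
c1ccc(Cc2ccncc2)cc1
c1ccc(CN2CCNCC2)cc1
c1ccc(OCC2CCCCC2)cc1
c1ccc(NC2CCCCC2)cc1
c1cnc(N2CCNCC2)nc1
c1ccc(-n2cccc2)cc1
c1ccc(-n2ccnc2)cc1
c1ccc(Cn2cccc2)cc1
c1ccc(Cc2ccc3ccccc3c2)cc1
c1ccc(Cc2cccs2)cc1
c1ccc(Cc2ccco2)cc1
c1ccc(-c2nccs2)cc1
c1ccc(-c2ncco2)cc1
c1ccc(-c2cn[nH]c2)cc1
c1ccc(-c2cnc[nH]2)cc1
c1ccc(-c2nc3ccccc3[nH]2)cc1
c1ccc(-c2nnc[nH]2)cc1
c1ccc(CCc2ccncc2)cc1
c1ccc(CCN2CCCCC2)cc1
c1ccc2c(c1)Cc1ccccc1-2
C1CCC(C2CCNCC2)CC1
C1CCC(N2CCCCC2)CC1
C1CN2CCC1CC2
c1ccc2cc3ccccc3cc2c1
c1ccc2c(c1)ccc1ccccc12
C1=CC2CCC1CC2
c1csc(-c2cccs2)c1
c1cnc2[nH]ccc2c1
C1CCC2(CC1)CCCCC2
C1CCC2(CC1)CCNCC2
C1CCC2(CC1)OCCO2
C1CCC2(CC1)CCOCC2
c1ncncn1
c1ccc(-c2ncncn2)cc1
c1ccc2c(c1)ccc1cccnc12
C1CCC2(C1)CCC2
c1ccn2cccc2c1
c1ccn2cncc2c1
c1ccc(-c2cccc3ccccc23)cc1
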