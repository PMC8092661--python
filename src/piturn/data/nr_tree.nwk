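(((SpNR2:2,Ctenophora_NR2A:2):1,(Trichoplax_HNF4:0.5,(HNF4_cnidarian:0.5,(HNF4_insect:0.5,HNF4_vertebrate:0.5):0.5):1):1):1,(((SpNR1_P1:0.5,SpNR1_P2:0.5):1,(SpNR1_P3:2,SpNR1_P4:0.5):1):1,((((RXR_vertebrate:0.5,RXR_bilaterian:0.5):0.5,RXR_cnidarian:0.5,USP:0.5):1,(Trichoplax_21656:2,(TR24_NR2CD:1,(FAX1:2,(DSF:2,(TLX:2,TLL:2):1):1,(PNR:1,NR2E1_cnidarian:0.5):1):1,(Hydractinia_NR2F:2,NR2F_KxxxE_cnidarian:1,(COUPTF1:1,COUPTF2:1,SVP:1,EAR2:1):1):1):1):1):1,((NR3_Hydra:2,Trichoplax_NR3:0.5,((ER_NR3:1,ERR_NR3:1):1,(AR_NR3:1,GR_NR3:1,MR_NR3:1,PR_NR3:1):1):1):1,(((SF1_NR5:1,LRH1_NR5:1):1,GCNF_NR6:1,NR9_cnidarian:1):1,(((TR_NR1:1,RAR_NR1:1):1,(PPAR_NR1:1,LXR_NR1:1):1,(VDR_NR1:1,EcR_NR1:1):1):1,(NGFIB_NR4:1,NURR1_NR4:1):1,NR7_leech:1,NR8_cnidarian:1):1):1):1):1):1);
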