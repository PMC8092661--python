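# Curated pi-turn character states across nuclear-receptor lineages,
# reconciled from sequence (RxxxE motif in helix H7) and structural evidence.
# Coding rules: crystal-structure evidence overrides the sequence motif
# (the COUP-TF and PNR groups carry the motif but their structures show no
# pi-turn); lineages whose only motif is a degraded variant (KxxxE, QxxxE,
# RxxxxxxE) are coded absent for the canonical character; motif-bearing
# lineages without structures are coded present; lineages with no usable
# evidence are coded unknown.
# taxon	state
SpNR2	absent
Ctenophora_NR2A	absent
Trichoplax_HNF4	present
HNF4_cnidarian	present
HNF4_insect	present
HNF4_vertebrate	present
SpNR1_P1	present
SpNR1_P2	present
SpNR1_P3	absent
SpNR1_P4	present
RXR_vertebrate	present
RXR_bilaterian	present
RXR_cnidarian	present
USP	present
Trichoplax_21656	absent
TR24_NR2CD	unknown
FAX1	absent
DSF	absent
TLX	absent
TLL	absent
PNR	absent
NR2E1_cnidarian	present
Hydractinia_NR2F	absent
NR2F_KxxxE_cnidarian	absent
COUPTF1	absent
COUPTF2	absent
SVP	absent
EAR2	absent
NR3_Hydra	absent
Trichoplax_NR3	present
ER_NR3	absent
ERR_NR3	absent
AR_NR3	absent
GR_NR3	absent
MR_NR3	absent
PR_NR3	absent
SF1_NR5	absent
LRH1_NR5	absent
GCNF_NR6	absent
NR9_cnidarian	absent
NGFIB_NR4	absent
NURR1_NR4	absent
NR7_leech	absent
NR8_cnidarian	absent
TR_NR1	absent
RAR_NR1	absent
PPAR_NR1	absent
LXR_NR1	absent
VDR_NR1	absent
EcR_NR1	absent
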