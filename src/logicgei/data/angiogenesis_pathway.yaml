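# Angiogenesis candidate gene-pathway: 34 genes, 257 SNPs, 9 sub-pathway boxes.
# Published rsIDs are real; filler SNP identifiers (rs<GENE><nn>) are SYNTHETIC
# placeholders standing in for the non-deposited tagSNP panel.
genes:
  VEGFA: [rsVEGFA01, rsVEGFA02, rsVEGFA03, rsVEGFA04, rsVEGFA05, rsVEGFA06, rsVEGFA07, rsVEGFA08, rsVEGFA09, rsVEGFA10]
  FLT1: [rsFLT101, rsFLT102, rsFLT103, rsFLT104, rsFLT105, rsFLT106, rsFLT107, rsFLT108, rsFLT109, rsFLT110]
  KDR: [rs6838752, rsKDR01, rsKDR02, rsKDR03, rsKDR04, rsKDR05, rsKDR06, rsKDR07, rsKDR08, rsKDR09, rsKDR10, rsKDR11]
  HIF1A: [rsHIF1A01, rsHIF1A02, rsHIF1A03, rsHIF1A04, rsHIF1A05, rsHIF1A06, rsHIF1A07, rsHIF1A08]
  PDGFB: [rs4821877, rsPDGFB01, rsPDGFB02, rsPDGFB03, rsPDGFB04, rsPDGFB05, rsPDGFB06, rsPDGFB07]
  TEK: [rsTEK01, rsTEK02, rsTEK03, rsTEK04, rsTEK05, rsTEK06, rsTEK07, rsTEK08]
  TGFB1: [rsTGFB101, rsTGFB102, rsTGFB103, rsTGFB104, rsTGFB105, rsTGFB106, rsTGFB107]
  TGFBR1: [rsTGFBR101, rsTGFBR102, rsTGFBR103, rsTGFBR104, rsTGFBR105, rsTGFBR106, rsTGFBR107]
  IGF1R: [rs2139924, rsIGF1R01, rsIGF1R02, rsIGF1R03, rsIGF1R04, rsIGF1R05, rsIGF1R06, rsIGF1R07, rsIGF1R08, rsIGF1R09, rsIGF1R10, rsIGF1R11]
  IRS1: [rsIRS101, rsIRS102, rsIRS103, rsIRS104, rsIRS105, rsIRS106]
  EGFR: [rs17151957, rsEGFR01, rsEGFR02, rsEGFR03, rsEGFR04, rsEGFR05, rsEGFR06, rsEGFR07, rsEGFR08, rsEGFR09]
  EGR2: [rs2295814, rs224082, rsEGR201, rsEGR202, rsEGR203, rsEGR204]
  CXCL8: [rsCXCL801, rsCXCL802, rsCXCL803, rsCXCL804, rsCXCL805]
  CXCR1: [rs1008562, rsCXCR101, rsCXCR102, rsCXCR103, rsCXCR104]
  CXCR2: [rsCXCR201, rsCXCR202, rsCXCR203, rsCXCR204, rsCXCR205]
  IL1A: [rsIL1A01, rsIL1A02, rsIL1A03, rsIL1A04, rsIL1A05, rsIL1A06]
  IL1B: [rsIL1B01, rsIL1B02, rsIL1B03, rsIL1B04, rsIL1B05, rsIL1B06]
  TNF: [rs1800630, rsTNF01, rsTNF02, rsTNF03, rsTNF04, rsTNF05]
  NFKB1: [rsNFKB101, rsNFKB102, rsNFKB103, rsNFKB104, rsNFKB105, rsNFKB106, rsNFKB107, rsNFKB108]
  VDR: [rsVDR01, rsVDR02, rsVDR03, rsVDR04, rsVDR05, rsVDR06, rsVDR07, rsVDR08, rsVDR09, rsVDR10]
  MMP1: [rs470215, rsMMP101, rsMMP102, rsMMP103, rsMMP104, rsMMP105, rsMMP106]
  MMP3: [rsMMP301, rsMMP302, rsMMP303, rsMMP304, rsMMP305, rsMMP306, rsMMP307]
  MMP7: [rsMMP701, rsMMP702, rsMMP703, rsMMP704, rsMMP705, rsMMP706]
  MMP9: [rsMMP901, rsMMP902, rsMMP903, rsMMP904, rsMMP905, rsMMP906, rsMMP907, rsMMP908]
  BMP1: [rsBMP101, rsBMP102, rsBMP103, rsBMP104, rsBMP105, rsBMP106, rsBMP107]
  BMP2: [rsBMP201, rsBMP202, rsBMP203, rsBMP204, rsBMP205, rsBMP206, rsBMP207]
  BMP4: [rsBMP401, rsBMP402, rsBMP403, rsBMP404, rsBMP405, rsBMP406, rsBMP407]
  BMPR1A: [rsBMPR1A01, rsBMPR1A02, rsBMPR1A03, rsBMPR1A04, rsBMPR1A05, rsBMPR1A06, rsBMPR1A07, rsBMPR1A08]
  BMPR1B: [rsBMPR1B01, rsBMPR1B02, rsBMPR1B03, rsBMPR1B04, rsBMPR1B05, rsBMPR1B06, rsBMPR1B07, rsBMPR1B08]
  BMPR2: [rsBMPR201, rsBMPR202, rsBMPR203, rsBMPR204, rsBMPR205, rsBMPR206, rsBMPR207, rsBMPR208]
  GDF10: [rsGDF1001, rsGDF1002, rsGDF1003, rsGDF1004, rsGDF1005, rsGDF1006, rsGDF1007]
  TLR2: [rs7656411, rsTLR201, rsTLR202, rsTLR203, rsTLR204, rsTLR205, rsTLR206, rsTLR207]
  TLR3: [rsTLR301, rsTLR302, rsTLR303, rsTLR304, rsTLR305, rsTLR306]
  TLR4: [rs1927911, rs11536889, rsTLR401, rsTLR402, rsTLR403, rsTLR404, rsTLR405, rsTLR406]
subpathways:
  vegf_signaling: [VEGFA, FLT1, KDR, HIF1A]
  pdgf_tek: [PDGFB, TEK]
  tgfb: [TGFB1, TGFBR1]
  igf_egfr: [IGF1R, IRS1, EGFR, EGR2]
  chemokine: [CXCL8, CXCR1, CXCR2]
  cytokine_nfkb: [IL1A, IL1B, TNF, NFKB1, VDR]
  mmp: [MMP1, MMP3, MMP7, MMP9]
  bmp: [BMP1, BMP2, BMP4, BMPR1A, BMPR1B, BMPR2, GDF10]
  tlr: [TLR2, TLR3, TLR4]
chromosome:
  VEGFA: 6p21.1
  FLT1: 13q12.3
  KDR: 4q12
  HIF1A: 14q23.2
  PDGFB: 22q13.1
  TEK: 9p21.2
  TGFB1: 19q13.2
  TGFBR1: 9q22.33
  IGF1R: 15q26.3
  IRS1: 2q36.3
  EGFR: 7p11.2
  EGR2: 10q21.3
  CXCL8: 4q13.3
  CXCR1: 2q35
  CXCR2: 2q35
  IL1A: 2q14.1
  IL1B: 2q14.1
  TNF: 6p21.33
  NFKB1: 4q24
  VDR: 12q13.11
  MMP1: 11q22.2
  MMP3: 11q22.2
  MMP7: 11q22.2
  MMP9: 20q13.12
  BMP1: 8p21.3
  BMP2: 20p12.3
  BMP4: 14q22.2
  BMPR1A: 10q23.2
  BMPR1B: 4q22.3
  BMPR2: 2q33.1
  GDF10: 10q11.22
  TLR2: 4q31.3
  TLR3: 4q35.1
  TLR4: 9q33.1
alleles:
  rs4821877: {minor: C, major: T}
  rs2139924: {minor: A, major: G}
  rs1800630: {minor: A, major: C}
  rs470215: {minor: T, major: C}
  rs1927911: {minor: T, major: C}
  rs11536889: {minor: C, major: G}
  rs2295814: {minor: A, major: G}
  rs224082: {minor: A, major: G}
  rs6838752: {minor: T, major: C}
  rs1008562: {minor: C, major: G}
  rs7656411: {minor: T, major: G}
  rs17151957: {minor: A, major: G}
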