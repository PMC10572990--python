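protein_a	protein_b	confidence
Fkbp1a	Hspa1b	0.88
Fkbp1a	Hspa2	0.79
Hspa1b	Hspa2	0.93
Hspa1b	Pdia3	0.72
Hspa1b	Park7	0.64
Hspa1b	Prdx1	0.69
Hspa1b	Rab4a	0.52
Park7	Pdia3	0.61
Park7	Prdx1	0.70
Park7	Atp6v1a	0.57
Prdx1	Gstm1	0.76
Prdx1	Gstp1	0.81
Eno2	Hspa1b	0.62
Eno2	Fkbp1a	0.58
Fkbp1a	Dbn1	0.53
Eno2	Park7	0.55
Eno2	Atp6v1a	0.51
Eno2	Gstp1	0.53
Gpi	Gapdhs	0.89
Gapdhs	Eno2	0.91
Eno2	Pklr	0.84
Pklr	Cs	0.63
Cs	Acat1	0.77
Cs	Got2	0.68
Got2	Glul	0.74
Glul	Prdx1	0.56
Fkbp1a	Ppp1cc	0.59
Hspa1b	Ppp2cb	0.54
Ppfia3	Ppp2cb	0.65
Ppfia3	Ppp2r1a	0.67
Ppp2cb	Ppp2r1a	0.86
Eno2	Thy1	0.52
Eno2	Tagln3	0.54
Eno2	Gap43	0.58
Tagln3	Dbn1	0.73
Gap43	Marcks	0.82
Acta1	Dbn1	0.66
Gnal	Gnb2	0.87
Gna12	Gnb2	0.85
Gnb2	Ppp2r1a	0.51
Septin8	Septin10	0.90
Rab37	Bbx	0.60
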