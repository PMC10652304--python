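gene_name	protein_name	uniprot_id	community	old_sign	young_sign	css
Calr	Calreticulin	P14211	Phospholipase A2 inhibition	-1	0	1.00
Rpl13a	60S ribosomal protein L13a	P19253	Metabolic stress response	0	0	0.94
Fbn1	Fibrillin-1	Q61554	Collagen and ECM biosynthesis	-1	-1	0.89
Ywhae	14-3-3 protein epsilon	P62259	Metabolic stress response	-1	0	0.89
Acan	Aggrecan core protein	Q61282	Collagen and ECM biosynthesis	-1	1	0.85
Canx	Calnexin	P35564	Metabolic stress response	-1	0	0.82
Hist1h4j	Histone H4	P62806	Metabolic stress response	-1	0	0.81
Tnnc2	Troponin C	P20801	Contractile-like	0	0	0.78
H3f3a	Histone H3.3	P84244	Metabolic stress response	0	0	0.75
Ywhaz	14-3-3 protein zeta/delta	P63101	Metabolic stress response	1	1	0.71
Gapdh	Glyceraldehyde-3-phosphate dehydrogenase	A0A0A0MQF6	Phospholipase A2 inhibition	1	0	0.66
Rps8	40S ribosomal protein S8	P62242	Metabolic stress response	0	0	0.64
Hist2h3c2	Histone H3.2	P84228	Metabolic stress response	-1	0	0.61
Hist1h3g	Histone H3.1	P68433	Metabolic stress response	0	0	0.60
Hspa4	Heat shock 70 kDa protein 4	Q3U2G2	Metabolic stress response	0	0	0.60
Sptan1	Spectrin alpha chain	A3KGU7	Contractile-like	0	0	0.55
Tpm1	Tropomyosin alpha-1 chain	P58771	Contractile-like	1	-1	0.55
Actb	Actin, cytoplasmic 1 (Beta-actin)	P60710	Metabolic stress response	0	0	0.54
Rps11	40S ribosomal protein S11	P62281	Metabolic stress response	0	0	0.52
Actn4	Alpha-actinin-4	P57780	Contractile-like	-1	0	0.51
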