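# 16 Archaeplastida species panel.
# columns: code, lineage_rank (1 = earliest-diverging), lineage group, full name.
# Table presence strings elsewhere use the *column* order At Os Pa Sm Pp Mp Nm Kf Mr Mpu Ot Ol Cv Cr Vc Cp.
code	lineage_rank	lineage	name
Cp	1	glaucophyta	Cyanophora paradoxa
Ot	2	chlorophyta	Ostreococcus tauri
Ol	3	chlorophyta	Ostreococcus lucimarinus
Mpu	4	chlorophyta	Micromonas pusilla
Mr	5	chlorophyta	Micromonas RCC299
Cv	6	chlorophyta	Chlorella vulgaris
Cr	7	chlorophyta	Chlamydomonas reinhardtii
Vc	8	chlorophyta	Volvox carteri
Kf	9	charophyta	Klebsormidium flaccidum
Nm	10	charophyta	Nitella mirabilis
Mp	11	marchantiophyta	Marchantia polymorpha
Pp	12	bryophyta	Physcomitrella patens
Sm	13	pteridophyta	Selaginella moellendorffii
Pa	14	gymnosperm	Picea abies
Os	15	monocot	Oryza sativa
At	16	eudicot	Arabidopsis thaliana
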