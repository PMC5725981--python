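# Architecture catalog for SET-domain protein classification in 16 Archaeplastida.
#
# One record per architecture type.  columns:
#   label     class/subclass/subdivision code (e.g. II-2A) or V-<kind>
#   backbone  hyphen-joined ordered (N->C) signature domain names
#   extras    comma-separated domains that may co-occur without changing the label
#             ('-' = none recorded)
#   presence  16-character +/- phyletic profile in the species column order
#             At Os Pa Sm Pp Mp Nm Kf Mr Mpu Ot Ol Cv Cr Vc Cp
#
# Class I (E(z)) variants are transcribed from schematic domain organisations and
# carry invented numeric ids I-1..I-7; their phyletic profiles are reconstructed
# from the prose (PreSET in Os/Sm; vanadium-binding in Pp/Mp; CSR and MSL
# Ostreococcus-specific; SANT monocot-only; no E(z) in Cp or Vc).
# Class V rows encode rules, not literal backbones: they are matched by marker
# domains (Rubis_subs_bind, TPR) or by homology fallback, never by exact
# architecture comparison, and carry no tabulated phyletic profile.
label	backbone	extras	presence
I-1	TCR-SET	-	+-++++++++--++--
I-2	SANT-TCR-SET	-	-+--------------
I-3	TCR-PreSET-SET	-	-+-+------------
I-4	TCR-Vn-SET	-	----++----------
I-5	CSR-TCR-SET	-	----------++----
I-6	MSL-TCR-SET	-	----------++----
I-7	TCR-ALDH_SF-SET	-	+----+----------
II-1A	AWS-SET	TUDOR,PLN03081	++++-++-+-++---+
II-1B	AWS-SET-PostSET	-	-------+----+---
II-2A	PHD-PHD-PHD-AWS-SET	-	----+++---------
II-2B	PHD-AWS-SET	-	+---------------
II-3A	ZnF_C2H2-AWS-SET-PostSET	ATP11,PHA03420,CITED,FAM196,SRI	++-+++-+--------
II-3B	ZnF_C2H2-AWS-SET	PHA,SOX,Drf_FM1,Me425_SD1	----++----------
II-3C	ZnF_C2H2-AWS-SET-ZnF_C2H2-ZnF_C2H2	-	--------+-------
II-Orphan	SET	LIM	+---++-+-++-++++
III-1A	PWWP-FYR-PHD-PHD-SET	TUDOR	+--++++------+--
III-1B	PWWP-FYR-PHD-SET	-	---+--------+---
III-1C	FYR-PHD-PHD-SET	-	------+-------+-
III-1D	ZnF_C2H2-PHD-PHD-PHD-PHD-PHD-FYR-SET-PostSET	-	-------+--------
III-1E	PWWP-FYR-PHD-PHD-SET-PostSET	TUDOR,UDS	-+--------------
III-2A	PWWP-PHD-PHD-PHD-SET	COG5141	++++-+----------
III-2B	PWWP-PHD-PHD-PHD-SET-PostSET	-	----+--+--------
III-2C	PWWP-PHD-HMGb-SAND-PHD-PHD-ZnF_C2H2-SET-PostSET	NHPGB	--------+-++----
III-2D	PWWP-AWS-SET	TUDOR	-------------+--
III-3A	PHD-PHD-SET	Agnet	-+-++--+-+-+----
III-3B	PHD-PHD-SET-PostSET	DUF3839,Jas	----++-------++-
III-3C	PHD-SET	BAH	+++-+-+--+------
III-3D	PHD-PreSET-SET	-	-----+----------
III-3E	PHD-SET-PostSET	-	------+---------
III-3F	PHD-HMG-SET	-	---------+------
III-4A	ZnF_C2H2-GYF-HMGCOA-SET-PostSET	PTZ,GY,MM_COA	---+------------
III-4B	SET-PostSET	TUDOR	-++--+++----++-+
III-Orphan	SET	-	++--------------
IV-1A	SRA-PreSET-SET	DUF3574,Treacle,PPR,Pinin_SDK,COG3440	+++++-++-+--+++-
IV-1B	SRA-SET	-	---------+--+---
IV-1C	SRA-PreSET-SET-SET	-	-------------+--
IV-2A	PreSET-SET	LaMG,COG5281	++++++++-+------
IV-2B	PHD-PreSET-SET	TPR	---+------------
IV-2C	ZnF_C2H2-ZnF_C2H2-PreSET-SET-PostSET	-	-----+----------
IV-2D	WIYLD-PreSET-SET	DUF5102,CNDH2_M2	+++--+----------
IV-2E	PreSET-SET-PostSET	-	-+----+---------
IV-2F	ZnF-PreSET-SET	-	-++-------------
IV-2G	PreSET-AWS-SET	-	+---------------
IV-Orphan	SET	-	----++-+-+++++++
V-SETD	Rubis_subs_bind-SET	-	----------------
V-TPR	TPR-SET	-	----------------
V-Orphan	SET	RCC1,bHLH-MYC,HLH,BASP1,rp1A,DUF4239	----------------
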