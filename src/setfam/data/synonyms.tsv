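# Domain-name synonym map: PFAM / NCBI-CDD aliases -> canonical names used in the
# architecture catalog.  Matching is case-insensitive; unlisted names pass through.
# columns: alias, canonical
alias	canonical
Post-SET	PostSET
Post_SET	PostSET
Pre-SET	PreSET
Pre_SET	PreSET
zf-C2H2	ZnF_C2H2
zf_C2H2	ZnF_C2H2
Zf-C2H2	ZnF_C2H2
SAD_SRA	SRA
YDG	SRA
YDG_SRA	SRA
SAD	SRA
Rubisco_LSMT	Rubis_subs_bind
Rubis-subs-bind	Rubis_subs_bind
Rubisco_subs_bind	Rubis_subs_bind
LSMT	Rubis_subs_bind
Tesmin	TCR
TSO1	TCR
Tesmin_TSO1	TCR
ALDH-SF	ALDH_SF
TPR_1	TPR
TPR_2	TPR
TPR_REGION	TPR
PHD_SF	PHD
PHD1	PHD
Ephd	PHD
PHD_NSD	PHD
HMG_box	HMGb
HMG-box	HMGb
SET_domain	SET
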