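drug	target	class	clinical_status
AEW541	IGF-1R	Kinase	Preclinical
AZD0530	Src, Abl/Bcr-Abl, EGFR	Kinase	Phase II
AZD6244	MEK	Kinase	Phase II
Erlotinib	EGFR	Kinase	Launched
Lapatinib	EGFR, HER2	Kinase	Launched
Nilotinib	Abl/Bcr-Abl	Kinase	Launched
PD0325901	MEK	Kinase	Discontinued
PD0332991	CDK4/6	Kinase	Phase II
PF2341066	c-MET, ALK	Kinase	Launched
PHA665752	c-MET	Kinase	Preclinical
PLX4720	RAF	Kinase	Preclinical
RAF265	Raf kinase B, KDR	Kinase	Phase I
Sorafenib	Flt3, C-KIT, PDGFRbeta, RET, Raf kinase B, Raf kinase C, VEGFR-1, KDR, FLT4	Kinase	Launched
TAE684	ALK	Kinase	Preclinical
TKI258	EGFR, FGFR1, PDGFRbeta, VEGFR-1, KDR	Kinase	Phase III
ZD6474	Abl, EGFR, Flt3, C-KIT, RET, VEGFR-1, KDR, FLT4	Kinase	Launched
Irinotecan	Topoisomerase I	Cytotoxic	Launched
Paclitaxel	Beta-tubulin	Cytotoxic	Launched
Topotecan	Topoisomerase I	Cytotoxic	Launched
17AAG	HSP90	Other	Phase III
L685458	Gamma Secretase	Other	Preclinical
LBW242	IAP	Other	Preclinical
Nutlin3	MDM2	Other	Preclinical
Panobinostat	HDAC	Other	Registered
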