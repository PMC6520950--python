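pathway	gene
DRR	ALKBH2
DRR	ALKBH3
DRR	MGMT
BER	APEX1
BER	APEX2
BER	APTX
BER	FEN1
BER	LIG1
BER	LIG3
BER	MBD4
BER	MPG
BER	MUTYH
BER	NEIL1
BER	NEIL2
BER	NEIL3
BER	NTHL1
BER	OGG1
BER	PARP1
BER	PARP2
BER	PCNA
BER	PNKP
BER	POLB
BER	POLD1
BER	POLE
BER	POLL
BER	WRN
BER	SMUG1
BER	TDG
BER	UNG
BER	XRCC1
NHEJ	DCLRE1C
NHEJ	XRCC6
NHEJ	XRCC5
NHEJ	LIG4
NHEJ	NHEJ1
NHEJ	POLM
NHEJ	PRKDC
NHEJ	XRCC4
MMR	EXO1
MMR	MLH1
MMR	MLH3
MMR	MSH2
MMR	MSH3
MMR	MSH6
MMR	PMS1
MMR	PMS2
TLS	POLH
TLS	POLI
TLS	POLK
TLS	POLN
TLS	POLQ
TLS	REV1
TLS	REV3L
DDS	ATM
DDS	ATR
DDS	ATRIP
DDS	BLM
DDS	BRCA1
DDS	CCNH
DDS	CDK7
DDS	CDKN1A
DDS	CHEK1
DDS	CHEK2
DDS	COPS5
DDS	DCLRE1A
DDS	DCLRE1B
DDS	FANCA
DDS	FANCC
DDS	GPS1
DDS	HUS1
DDS	MDC1
DDS	MNAT1
DDS	MRE11A
DDS	NBN
DDS	RAD1
DDS	RAD17
DDS	RAD18
DDS	RAD23A
DDS	RAD50
DDS	RAD9A
DDS	RFC1
DDS	RFC2
DDS	RFC3
DDS	RFC4
DDS	RFC5
DDS	TOPBP1
DDS	TP53
HRR	BRCA2
HRR	FAAP24
HRR	EME1
HRR	EME2
HRR	FANCB
HRR	FANCD2
HRR	FANCE
HRR	FANCF
HRR	FANCG
HRR	FANCI
HRR	FANCL
HRR	MSH4
HRR	MSH5
HRR	MUS81
HRR	RAD51
HRR	RAD52
NER	ERCC8
NER	ERCC6
NER	CUL4A
NER	DDB1
NER	DDB2
NER	ERCC1
NER	GTF2H1
NER	GTF2H2
NER	GTF2H3
NER	GTF2H4
NER	GTF2H5
NER	MMS19
NER	RAD23B
NER	RPA1
NER	XPA
NER	ERCC3
NER	XPC
NER	ERCC2
NER	ERCC4
NER	ERCC5
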