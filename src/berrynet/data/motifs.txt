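# Example catalog of degenerate cis-regulatory elements (IUPAC 6-8-mers)
# recognized by drought- and ripening-associated transcription-factor
# families. One motif per line, optional tab-separated label.
ACGTGKC	ABRE
CACGTG	G-box
RCCGAC	DRE-core
RCCGACA	DRE
RYCGAC	DRE-related
MACCGMCW	DRE-related
CATGTG	NACR
TTRCGT	NACR
GCCGCC	GCC-box
CCGTTA	MYB
TGTCGG	AuxRE-ETT
ACACTA	ZAT6
TTACGTGT	ABRE-like
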