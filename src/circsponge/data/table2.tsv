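gene	primer_name	sequence
GAPDH (Mouse)	Gapdh-F	TCCTGCACCACCAACTGCTTAG
	Gapdh-R	AGTGGCAGTGATGGCATGGAC
circRNA.7079	CUST_110069_PI435794180-F	CCCGCTTCAATGAGAACAACA
	CUST_110069_PI435794180-R	GGAGCCTGTCCTGGTTATTGTC
circRNA.12884	CUST_118563_PI435794180-F	CTTGTGTCCAAGTGAATGAATGG
	CUST_118563_PI435794180-R	GCCGGTGTCGAGTGAAGAA
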