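set	group	pka
embl	Nterm	8.6
embl	Cterm	3.6
embl	C	8.5
embl	D	3.9
embl	E	4.1
embl	H	6.5
embl	K	10.8
embl	R	12.5
embl	Y	10.1
dtaselect	Nterm	8.0
dtaselect	Cterm	3.1
dtaselect	C	8.5
dtaselect	D	4.4
dtaselect	E	4.4
dtaselect	H	6.5
dtaselect	K	10.0
dtaselect	R	12.0
dtaselect	Y	10.0
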