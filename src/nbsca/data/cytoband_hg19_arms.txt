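chr1	0	121500000	p	gneg
chr1	121500000	125000000	p11.1	acen
chr1	125000000	128900000	q11	acen
chr1	128900000	249250621	q	gneg
chr2	0	91800000	p	gneg
chr2	91800000	93300000	p11.1	acen
chr2	93300000	95700000	q11.1	acen
chr2	95700000	243199373	q	gneg
chr11	0	51600000	p	gneg
chr11	51600000	53700000	p11.11	acen
chr11	53700000	55700000	q11	acen
chr11	55700000	135006516	q	gneg
chr17	0	22200000	p	gneg
chr17	22200000	24000000	p11.1	acen
chr17	24000000	25800000	q11.1	acen
chr17	25800000	81195210	q	gneg
chr19	0	24400000	p	gneg
chr19	24400000	26500000	p11	acen
chr19	26500000	28600000	q11	acen
chr19	28600000	59128983	q	gneg
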