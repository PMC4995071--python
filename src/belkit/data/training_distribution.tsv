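# Published category distribution of the BioCreative V BEL track
# training corpus (BEL_Extraction training corpus): counts per term,
# function and relationship type, plus corpus size.
# Columns: category, key, count.
size	sentences	6353
size	statements	11066
term	P	19918
term	A	1927
term	bp	877
term	path	244
function	act	6332
function	pmod	1411
function	complex	750
function	tloc	406
function	deg	205
function	sub	23
function	trunc	6
relationship	increases	8112
relationship	decreases	2956
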