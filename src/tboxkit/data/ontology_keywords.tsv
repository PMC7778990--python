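# Keyword -> amino-acid family table for downstream-gene ontology matching.
# Keywords are matched case-insensitively as substrings; longer keywords take
# precedence and mask the text they cover (so 'isoleucyl' never also fires
# 'leucyl').  Extend freely with gene symbols or pathway terms.
# keyword	family
alanyl	A
arginyl	R
asparaginyl	N
aspartyl	D
cysteinyl	C
glutaminyl	Q
glutamyl	E
glycyl	G
histidyl	H
isoleucyl	I
leucyl	L
lysyl	K
methionyl	M
phenylalanyl	F
prolyl	P
seryl	S
threonyl	T
tryptophanyl	W
tyrosyl	Y
valyl	V
alanine	A
arginine	R
asparagine	N
aspartate	D
aspartic acid	D
cysteine	C
glutamine	Q
glutamate	E
glutamic acid	E
glycine	G
histidine	H
isoleucine	I
leucine	L
lysine	K
methionine	M
phenylalanine	F
proline	P
serine	S
threonine	T
tryptophan	W
tyrosine	Y
valine	V
alaS	A
argS	R
asnS	N
aspS	D
cysS	C
glnS	Q
gltX	E
glyQS	G
glyS	G
hisS	H
ileS	I
leuS	L
lysS	K
metS	M
pheS	F
proS	P
serS	S
thrS	T
trpS	W
tyrS	Y
valS	V
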