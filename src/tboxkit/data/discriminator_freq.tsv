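# Modal tRNA discriminator base per amino-acid family, used as fallback when
# the host organism provides no tRNA of the family.  Bundled defaults follow
# commonly reported bacterial discriminator preferences (editable; supply your
# own table derived from a tRNA survey for production use).
# family	modal_base
A	A
R	G
N	G
D	G
C	U
Q	G
E	A
G	A
H	C
I	A
L	A
K	A
M	A
F	A
P	C
S	G
T	A
W	G
Y	A
V	A
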