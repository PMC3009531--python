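# Default amino-acid property assignment (one residue per line).
# Columns: aa  charge  polarity  aromaticity  electronic  size
# charge:      positive | negative | neutral
# polarity:    polar | nonpolar
# aromaticity: aromatic | aliphatic | neither
# electronic:  strong-acceptor | strong-donor | acceptor | donor | neutral
# size:        small | medium | big
A	neutral	nonpolar	aliphatic	neutral	small
C	neutral	polar	neither	donor	small
D	negative	polar	neither	strong-acceptor	small
E	negative	polar	neither	strong-acceptor	medium
F	neutral	nonpolar	aromatic	donor	big
G	neutral	nonpolar	aliphatic	neutral	small
H	positive	polar	aromatic	donor	medium
I	neutral	nonpolar	aliphatic	neutral	medium
K	positive	polar	neither	strong-donor	big
L	neutral	nonpolar	aliphatic	neutral	medium
M	neutral	nonpolar	neither	donor	medium
N	neutral	polar	neither	acceptor	small
P	neutral	nonpolar	neither	neutral	small
Q	neutral	polar	neither	acceptor	medium
R	positive	polar	neither	strong-donor	big
S	neutral	polar	neither	acceptor	small
T	neutral	polar	neither	acceptor	small
V	neutral	nonpolar	aliphatic	neutral	medium
W	neutral	polar	aromatic	donor	big
Y	neutral	polar	aromatic	donor	big
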