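# factor=SRSF6	threshold=2.676
# Position weight matrix for the SR protein SRSF6 (SRp55), ESEfinder-style.
# Own-constructed weights with consensus UGCGUC, scaled so the consensus
# scores moderately above the published threshold.  Replace this file to use
# matrices from another source.
pos	A	C	G	U
1	-0.36	0.16	-0.44	0.48
2	-0.20	-0.40	0.52	-0.32
3	-0.44	0.48	-0.36	0.20
4	0.08	-0.40	0.56	-0.52
5	-0.32	0.24	-0.40	0.44
6	0.12	0.52	-0.36	-0.44
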