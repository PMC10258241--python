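# factor=SRSF1	threshold=1.956
# Position weight matrix for the SR protein SRSF1 (SF2/ASF), ESEfinder-style.
# Own-constructed weights encoding the degenerate SELEX consensus SRSASGA
# (S=C/G, R=A/G), scaled so the consensus scores moderately above the
# published threshold (as for the original matrices, a single unfavorable
# substitution can abolish a site).  Replace this file to use matrices from
# another source.
pos	A	C	G	U
1	-0.45	0.36	0.30	-0.54
2	0.33	-0.36	0.24	-0.45
3	-0.30	0.30	0.39	-0.48
4	0.42	-0.15	0.06	-0.51
5	-0.33	0.27	0.36	-0.42
6	-0.24	-0.27	0.45	-0.57
7	0.39	0.03	-0.12	-0.36
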