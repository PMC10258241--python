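# factor=SRSF2	threshold=2.383
# Position weight matrix for the SR protein SRSF2 (SC35), ESEfinder-style.
# Own-constructed weights encoding the degenerate consensus GRYYCSYR, scaled
# so the consensus scores moderately above the published threshold.
# Replace this file to use matrices from another source.
pos	A	C	G	U
1	-0.19	-0.32	0.42	-0.38
2	0.22	-0.35	0.32	-0.42
3	-0.38	0.35	-0.29	0.26
4	-0.32	0.38	-0.35	0.22
5	-0.10	0.45	-0.26	0.06
6	-0.38	0.29	0.35	-0.45
7	-0.29	0.26	-0.32	0.32
8	0.29	-0.35	0.19	-0.38
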