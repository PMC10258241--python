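# factor=SRSF5	threshold=2.67
# Position weight matrix for the SR protein SRSF5 (SRp40), ESEfinder-style.
# Own-constructed weights with consensus ACAGCCA, scaled so the consensus
# scores moderately above the published threshold.  Replace this file to use
# matrices from another source.
pos	A	C	G	U
1	0.38	0.23	-0.30	-0.38
2	-0.15	0.46	-0.38	0.11
3	0.49	-0.34	0.19	-0.46
4	-0.23	-0.38	0.53	-0.49
5	-0.42	0.38	0.30	-0.46
6	-0.30	0.42	-0.38	0.15
7	0.46	-0.27	0.11	-0.42
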