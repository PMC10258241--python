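name	target_exon	aso	mmaso
ASO_30	30	ACACUUUGUGGAGCUGUGAAGG	ACACUUUGUAUAACUGUUAAGG
ASO_30E	30	GCUGUAUCCAUUUAAGCUGCG	GCUAUAUCCAUUUAAAAUACG
ASO_31B	31	CUUCUUGUGGAGUAGAGAUGUU	CUUAUUGUGUAUUAAAGAUGUU
ASO_39D	39	CUGGAGUUGGUAUCUGGGA	CUGAAUUUGAUAUCUGAGA
ASO_40A	40	UAGCUUAACGAUGCAGAAGGAUU	UAGAUUAAUGAUGCAUAAGUAUU
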