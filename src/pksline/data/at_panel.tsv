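# synthetic AT specificity reference panel; diagnostic columns are
# 0-based offsets on the packaged AT scaffold (the alignment anchor)
seq_id	specificity
malAT1	malonyl
malAT2	malonyl
malAT3	malonyl
malAT4	malonyl
mmAT1	methylmalonyl
mmAT2	methylmalonyl
mmAT3	methylmalonyl
mmAT4	methylmalonyl
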