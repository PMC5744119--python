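peptide_id	family	theoretical_mass
TatNaTBet03	Sodium toxins	5196.79
TatNaTBet08	Sodium toxins	6195.85
TatKTxAlp10	Potassium toxins	3607.43
TatKTxAlp12	Potassium toxins	4114.86
TatCaTClc01	Calcium toxins	3788.48
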