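contribution,water_model,salt_mM,printed
sep_term_IC,TIP3P,81,-20.0 ± 1.4
sep_term_IC,TIP3P,177,-15.4 ± 2.2
sep_term_IC,TIP3P,450,-9.9 ± 1.3
sep_term_IC,TIP4P-D,81,-7.2 ± 5.2
sep_term_IC,TIP4P-D,177,-6.0 ± 2.0
sep_term_IC,TIP4P-D,450,-4.0 ± 1.1
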