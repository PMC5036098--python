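library	raw_reads	clean_reads	printed_clean_pct	unique_clean_reads	printed_unique_pct
G-ctl	6931266	6561741	94.7	2013956	29.0
G-cd	7453307	6945431	93.2	1394044	18.7
Y-ctl	6219546	5790967	93.1	2076409	33.4
Y-cd	6553483	5631677	85.9	1061349	16.2
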