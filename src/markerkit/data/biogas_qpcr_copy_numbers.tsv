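sample_type	sample	gh48_copies_per_ul	gh48_sd	rrna16s_copies_per_ul	rrna16s_sd	printed_ratio_pct
raw_digestate	MS1	5.7e6	1.1e6	7.1e8	1.8e8	0.8
raw_digestate	MS2	4.8e6	3.1e5	1.5e9	3.6e8	0.3
raw_digestate	MS3	3.6e6	4.7e5	1.2e9	1.5e8	0.3
raw_digestate	MI	5.4e6	4.0e5	6.7e8	1.5e7	0.8
raw_digestate	TS	2.9e6	2.9e5	8.0e8	2.6e8	0.4
raw_digestate	TI	7.9e6	8.1e5	1.2e9	6.8e7	0.7
in_sacco	MS1	6.8e6	8.7e5	2.2e8	5.1e7	3.1
in_sacco	MS2	2.4e7	9.6e6	6.4e8	1.1e7	3.7
in_sacco	MS3	3.8e6	1.4e5	1.9e8	2.0e7	2.0
in_sacco	MI	9.1e4	1.3e4	7.8e6	8.4e5	1.2
in_sacco	TS	3.4e6	4.0e5	2.4e8	4.1e7	1.4
in_sacco	TI	5.8e6	1.5e6	1.7e8	1.4e7	3.5
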