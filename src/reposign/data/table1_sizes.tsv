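dataset_id	n_case	n_ctrl
GSE22619	10	10
GSE37283	15	5
GSE38713	30	13
GSE10191	8	11
GSE13367	17	10
GSE36807	15	7
GSE4183	9	8
GSE9686	5	8
GSE10616	10	11
GSE16879	24	6
GSE53306	28	12
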