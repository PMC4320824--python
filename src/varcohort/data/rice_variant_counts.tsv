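line_id	group	n_total	n_filtered	n_line_specific	n_ins	n_del	n_snp
50A	transgenic	19802	12706	798	88	222	488
51A	transgenic	19612	12586	619	54	224	341
55A	transgenic	19398	12736	842	96	263	483
WT1	wild_type	19103	12477	524	47	170	307
WT2	wild_type	20623	12927	826	79	282	465
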