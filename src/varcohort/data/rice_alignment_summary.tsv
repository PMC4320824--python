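line_id	group	total_reads	mapped_reads	read_length	covered_length
50A	transgenic	384384291	375891543	100	371762264
51A	transgenic	362591974	352782360	100	371570800
55A	transgenic	356620373	349808296	100	369691614
WT1	wild_type	342044404	332246878	100	371589770
WT2	wild_type	323436829	314249500	100	371575970
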