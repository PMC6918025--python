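gene_id	name	description	fpkm_dgalua	fpkm_gly	fpkm_dglc	fitness_dgalua	fitness_gly	fitness_dglc
RTO4_9841		Hexose transporter	4605	78	23	-2.3	0.2	-0.1
RTO4_11882	GAR1	Reductase	7667	64	118	-4.0	0.0	0.3
RTO4_12062	GaaB	L-Galactonic acid dehydratase	9846	57	26	-3.3	0.0	-0.4
RTO4_12061	GaaC	2-keto-3-deoxy-L-galactonate aldolase	6397	134	24	-5.1	-0.4	-0.3
RTO4_9774	GaaD	NADPH-dependent erythrose reductase	3981	699	524	-0.8	0.0	0.1
RTO4_11332	GAL7	Galactose-1-P uridyl transferase	330	58	55	-1.6	-0.1	-0.1
RTO4_13270		ZnCys transcription factor	93	12	9	-4.0	0.0	0.0
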