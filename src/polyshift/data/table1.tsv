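accession	name	z_T	z_NP	z_P	qpcr_NP	qpcr_P	change
At3g23430	Phosphate transport (PHO1)	0.59	1.58	-2.3	1.9	-15.8	Decrease
At4g02950	Ubiquitin family protein	-0.51	2.80	-2.2	-3.1	-6.8	Decrease
At4g20340	Transcription initiation factor (TFIIE)	1.15	2.95	-2.8	1.0	-6.2	Decrease
At3g55580	Regulator of chromosome condensation (RCC1)	0.65	2.5	-2.6	-2.6	-4.2	Decrease
At2g02860	Sucrose transporter 3 (SUC3)	0.97	1.6	-1.9	2.2	-3.4	Decrease
At2g30260	Component of the U2 snRNP complex (U2B'')	0.28	2.5	-2.6	5.6	-2.9	Decrease
At1g21630	Calcium ion binding, EF hand protein	-0.64	3.5	-2.6	3.2	-1.5	Decrease
At2g17630	Pyridoxal phosphate (PLP)-dependent transferase	1.25	2.5	-2.2	2.8	-1.4	Decrease
At1g78240	Tumorous shoot development 2 (TSD2)	0.88	1.6	-1.6	1.5	-1.0	Decrease
At2g27940	RING/U-box protein	-0.04	-1.98	1.8	-2.3	15.6	Increase
At2g28600	P-loop containing nucleoside tri-phosphate hydrolase	0.29	-2.09	1.8	-1.3	8.1	Increase
At1g68670	MYB-like transcription factor family	0.55	-1.8	1.8	1.7	4.3	Increase
At4g06746	Transcription factor ERF/AP2 DREB subfamily A-5 (RAP2.9)	1.63	-1.8	2.1	-1.9	1.9	Increase
At3g57600	Transcription factor ERF/AP2 DREB subfamily A-2 (ERF/AP2)	n.d.	-2.5	1.7	-1.5	1.9	Increase
At2g05710	Aconitase (ACO3)	-1.95	-3.2	2.6	-13.3	1.8	Increase
At5g61430	NAC domain containing protein (NAC5)	1.92	-1.8	2.3	-4.9	1.7	Increase
At1g6880	Transcription factor (BRC2)	-0.7	-1.7	1.6	-11.6	1.5	Increase
At4g18720	Transcription factor IIS protein	0.96	-2.7	3.2	-4.3	1.4	Increase
At5g15850	Transcription factor, constans-like 1 (COL1)	n.d.	-2.0	1.7	-2.2	1.3	Increase
At4g33250	Eukaryotic translation initiation factor 3 K (EIF3K)	n.d.	-1.8	2.6	5.1	4.9	Increase
At5g15630	Cobra-like4 (COBL4)	1.57	2.8	-1.6	6.2	1.4	l.c.
At5g01840	Ovate family protein 1 (OFP1)	0.59	3.6	-2.8	2.3	5.1	l.c.
At1g64580	Pentatricopeptide repeat-containing protein (PPR)	0.86	1.6	-2.0	2.7	6.3	l.c.
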