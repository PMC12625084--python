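# In-silico census of the 18 linseed trehalose-6-phosphate synthase (LuTPS)
# proteins: closest Arabidopsis ortholog used for naming, protein length (aa),
# molecular weight (kDa), isoelectric point, and predicted site counts
# (CK2 / PKC / TYR / cAMP phosphorylation, amidation, N-glycosylation).
gene_id	name	at_ortholog	length	mw_kda	pi	ck2	pkc	tyr	camp	amidation	asn_glycosylation
Lus10013694	LuTPS1.1	At1g78580	971	109.26	7.05	16	16	0	2	3	5
Lus10005559	LuTPS1.2	At1g78580	939	105.88	6.93	16	15	0	3	3	5
Lus10015243	LuTPS1.3	At1g78580	946	106.37	6.51	26	19	0	2	2	6
Lus10005412	LuTPS1.4	At1g78580	957	107.96	6.69	26	19	0	2	3	6
Lus10034585	LuTPS6.1	At1g68020	855	97.18	5.65	18	16	1	3	1	1
Lus10021805	LuTPS6.2	At1g68020	855	97.14	5.60	16	18	1	3	1	1
Lus10005425	LuTPS7.1	At1g06410	849	96.24	6.04	13	8	0	2	0	2
Lus10015231	LuTPS7.2	At1g06410	849	96.17	6.10	13	8	0	2	0	2
Lus10029258	LuTPS7.3	At1g06410	853	96.28	5.71	15	9	0	3	0	0
Lus10007311	LuTPS7.4	At1g06410	853	96.44	5.76	15	9	0	3	0	1
Lus10029821	LuTPS7.5	At1g06410	838	95.19	5.53	18	7	0	1	1	3
Lus10020741	LuTPS7.6	At1g06410	838	95.23	5.50	19	6	0	1	1	4
Lus10012990	LuTPS8.1	At1g70290	865	98.12	6.01	12	10	1	1	1	2
Lus10029175	LuTPS8.2	At1g70290	865	97.95	6.11	12	11	0	1	0	2
Lus10030853	LuTPS10.1	At1g60140	864	97.74	5.90	13	10	0	2	1	2
Lus10030635	LuTPS10.2	At1g60140	897	101.33	5.90	11	12	0	1	1	2
Lus10015509	LuTPS11.1	At2g18700	850	96.36	6.25	15	11	1	1	0	0
Lus10019982	LuTPS11.2	At2g18700	800	90.75	6.13	15	10	1	1	0	0
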