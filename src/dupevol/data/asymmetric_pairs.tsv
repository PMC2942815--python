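fast_id	fast_subs	slow_id	slow_subs	function
NM_182537	52	NM_182589	8	Serotonin receptor
NM_001083538	29	NM_001101	1	Actin beta
NM_002030	51	NM_001005738	15	Formyl peptide receptor
NM_001009562	77	NM_019844	34	Organic anion transporter
NM_001001659	32	NM_012365	12	Olfactory receptor
NM_000896	36	NM_001082	15	Cytochrome P450
NM_152631	64	NM_001013736	36	Unknown
NM_001004692	13	NM_001004695	2	Olfactory receptor
NM_145660	46	NM_145640	24	Apolipoprotein
NM_001006938	10	NM_001006933	1	Transcription elongation factor
NM_032098	48	NM_032099	27	Protocadherin gamma
NM_001004737	11	NM_001004736	2	Olfactory receptor
NM_001004743	37	NM_001005282	20	Olfactory receptor
NM_005557	40	NM_000526	8	Keratin 16
NM_020040	24	NM_177987	3	Tubulin, beta polypeptide
NM_002699	15	NM_006236	0	POU class 3 homeobox
NM_017534	64	NM_005963	27	Myosin, heavy chain
NM_001004482	19	NM_001004481	2	Olfactory receptor
NM_001004454	50	NM_001005236	20	Olfactory receptor
NM_001013435	12	NM_001015038	0	P antigen family
NM_000150	26	NM_002034	6	Fucosyltransferase
NM_001005479	27	NM_001005514	7	Olfactory receptor
NM_001005519	31	NM_054105	11	Olfactory receptor
NM_001005471	34	NM_030904	15	Olfactory receptor
NM_012373	17	NM_002551	5	Olfactory receptor
NM_032089	74	NM_014004	49	Protocadherin gamma
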