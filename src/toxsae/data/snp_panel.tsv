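rsid	endpoint	effect	effect_type	p	ld_group	ref
rs10519410	rectal_bleeding	3.7	OR	1.3e-6	.	lit1
rs17055178	rectal_bleeding	1.95	HR	6.2e-10	.	lit2
rs17599026	urinary_frequency	3.12	OR	4.16e-8	.	lit3
rs342442	urinary_frequency	0.51	OR	3.86e-7	.	lit3
rs8098701	urinary_frequency	2.41	OR	2.11e-6	.	lit3
rs7366282	urinary_frequency	3.2	OR	2.03e-6	.	lit3
rs10209697	urinary_frequency	2.66	OR	2.27e-6	.	lit3
rs4997823	urinary_frequency	0.49	OR	2.35e-6	.	lit3
rs7356945	urinary_frequency	1.74	OR	3.71e-6	.	lit3
rs6003982	urinary_frequency	0.51	OR	4.28e-6	.	lit3
rs10101158	urinary_frequency	1.8	OR	4.39e-6	.	lit3
rs7720298	decreased_stream	2.71	OR	3.21e-8	.	lit3
rs17362923	decreased_stream	2.7	OR	6.79e-7	.	lit3
rs76273496	decreased_stream	3.68	OR	2.71e-6	.	lit3
rs144596911	decreased_stream	3.6	OR	2.94e-6	.	lit3
rs62091368	decreased_stream	4.36	OR	3.95e-6	.	lit3
rs141342719	decreased_stream	3.5	OR	3.97e-6	.	lit3
rs673783	decreased_stream	2.49	OR	4.33e-6	.	lit3
rs10969913	decreased_stream	3.92	HR	2.9e-10	.	lit2
rs11122573	haematuria	1.92	HR	1.8e-8	.	lit2
rs708498	haematuria	0.24	OR	.	.	lit4
rs845552	haematuria	0.95	OR	.	.	lit4
rs1799983	nocturia	0.19	OR	.	.	lit4
rs1045485	nocturia	0.27	OR	.	.	lit4
rs10497203	overall_STAT	1.48	OR	8.84e-11	stat_block	lit5
rs7582141	overall_STAT	1.45	OR	4.64e-11	stat_block	lit5
rs6432512	overall_STAT	1.42	OR	1.97e-10	stat_block	lit5
rs264651	overall_STAT	1.49	OR	1.48e-7	stat_block	lit5
rs264588	overall_STAT	1.45	OR	3.08e-10	stat_block	lit5
rs264631	overall_STAT	1.43	OR	6.4e-10	stat_block	lit5
rs147596965	overall_STAT	1.95	OR	6.19e-8	.	lit3
rs77530448	overall_STAT	1.43	OR	7.36e-8	.	lit3
rs4906759	overall_STAT	1.73	OR	1.55e-7	.	lit3
rs71610881	overall_STAT	1.82	OR	5.41e-7	.	lit3
rs141799618	overall_STAT	1.55	OR	1.22e-6	.	lit3
rs2842169	overall_STAT	1.32	OR	1.45e-6	.	lit3
rs11219068	overall_STAT	1.32	OR	1.74e-6	.	lit3
rs8075565	overall_STAT	1.32	OR	2.20e-6	.	lit3
rs6535028	overall_STAT	1.34	OR	2.70e-6	.	lit3
rs4775602	overall_STAT	1.26	OR	3.20e-6	.	lit3
rs7829759	overall_STAT	1.39	OR	3.84e-6	.	lit3
rs79604958	overall_STAT	1.60	OR	4.33e-6	.	lit3
rs12591436	overall_STAT	1.20	OR	5.66e-6	.	lit3
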