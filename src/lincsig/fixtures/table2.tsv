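ensembl_id	symbol	discovery_log2fc	discovery_p	paired_log2fc	paired_p	tvn_log2fc	tvn_p
ENSG00000261039	RP11-417E7	7.04	1.47E-08	3.49	2.42E-03	7.11	6.45E-05
ENSG00000230838	AC093850	5.84	6.87E-08	9.72	1.19E-10	15.03	1.42E-11
ENSG00000224577	AC017048	3.26	4.31E-05	2.17	2.69E-02	1.03	4.56E-01
ENSG00000253364	RP11-731F5	2.52	4.88E-03	9.31	1.78E-09	13.17	1.16E-08
ENSG00000197308	GATA3-AS1	2.49	2.08E-05	8.27	6.36E-07	5.58	1.43E-02
ENSG00000259093	RP11-1112J20	2.20	6.87E-08	2.02	8.65E-07	2.78	4.02E-06
ENSG00000230615	RP5-1198O20	1.72	2.80E-04	6.53	1.75E-13	7.58	3.50E-09
ENSG00000253161	RP11-150O12	1.68	1.00E-03	4.61	4.12E-05	5.54	9.67E-04
ENSG00000245750	RP11-279F6	1.57	1.17E-03	4.96	1.63E-04	6.07	1.47E-03
ENSG00000214548	MEG3	-1.17	2.47E-07	-2.35	1.15E-07	-0.75	2.18E-01
ENSG00000237697	LINC00312	-1.18	9.13E-03	-3.10	1.24E-04	0.41	7.27E-01
ENSG00000267519	CTD-3252C9	-1.48	6.89E-11	-1.01	4.12E-05	1.33	2.00E-05
ENSG00000267272	RP5-1052I5	-1.56	2.64E-05	-3.02	2.65E-04	-2.37	3.67E-02
ENSG00000255455	RP11-890B15	-1.62	1.28E-04	-1.59	3.60E-04	-1.35	3.52E-02
ENSG00000234076	TPRG1-AS1	-1.74	3.52E-03	-1.93	1.12E-03	-3.37	2.06E-05
ENSG00000262728	AC123768	-1.82	4.90E-08	-1.58	1.27E-02	-3.01	2.80E-04
ENSG00000269930	RP11-932O9	-1.85	9.95E-07	-1.82	8.56E-05	-1.74	7.45E-03
ENSG00000260025	RP11-490M8	-2.15	1.10E-06	-1.99	1.18E-02	-2.78	6.05E-03
ENSG00000260807	RP11-161M6	-2.24	1.64E-06	-1.96	4.49E-02	-5.65	1.34E-05
ENSG00000231246	RP5-965F6	-2.32	4.87E-07	-3.42	5.22E-03	-2.94	7.71E-02
ENSG00000266176	RP11-855A2	-2.39	9.44E-04	-4.16	9.90E-05	0.16	9.21E-01
ENSG00000260693	AC026150	-2.44	1.08E-06	-1.81	3.04E-04	-1.19	8.99E-02
ENSG00000223477	LINC00842	-2.46	8.86E-08	-2.93	7.21E-04	-5.50	1.07E-06
ENSG00000182021	RP11-381O7	-2.57	2.33E-05	-3.26	1.17E-06	-3.67	8.14E-05
ENSG00000258498	DIO3OS	-2.68	1.01E-04	-3.34	2.49E-05	-3.76	9.62E-05
ENSG00000269936	MIR145	-2.70	9.87E-13	-1.34	5.52E-04	-1.61	1.80E-03
ENSG00000229645	LINC00341	-2.77	6.89E-11	-3.89	7.12E-06	-2.82	1.50E-02
ENSG00000261064	RP11-1000B6	-2.79	9.95E-07	-1.33	7.23E-03	-1.77	6.81E-03
ENSG00000229108	AC005550	-2.81	2.28E-05	-4.31	4.11E-04	-6.34	7.85E-05
ENSG00000267194	RP1-193H18	-2.81	2.97E-06	-2.32	1.43E-03	-3.05	7.26E-04
ENSG00000260124	RP4-791K14	-2.84	8.18E-06	-1.84	8.56E-06	-2.32	4.72E-05
ENSG00000224307	RP11-344B5	-3.10	7.24E-04	-2.07	2.87E-03	-1.88	3.44E-02
ENSG00000178947	LINC00086	-3.23	1.94E-09	-1.59	2.60E-02	-2.66	5.14E-03
ENSG00000259070	LINC00639	-3.45	2.88E-07	-2.30	8.87E-04	-3.48	1.40E-04
ENSG00000271239	RP11-238F2	-3.67	3.37E-06	-3.19	3.08E-02	-3.86	5.24E-02
ENSG00000262179	RP1-302G2	-4.26	6.95E-07	-5.21	3.39E-06	-4.74	1.56E-03
ENSG00000246430	RP11-16M8	-5.25	2.61E-06	-6.36	4.27E-09	-3.19	3.97E-02
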