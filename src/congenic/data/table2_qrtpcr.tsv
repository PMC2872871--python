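gene	region	microarray_ratio	qrtpcr_ratio	microarray_significant
Ptprr	nucleus_accumbens	2.22	2.28	1
Ptprr	amygdala	2.47	2.71	1
Ptprr	frontal_cortex	2.17	1.85	1
Ptprr	hippocampus	2.42	2.77	1
Ptprr	caudate_putamen	1.98	2.28	1
Copg2_IT	nucleus_accumbens	-3.97	-2.45	1
Copg2_IT	amygdala	-28.29	-1.73	1
Copg2_IT	frontal_cortex	-31.36	-1.61	1
Copg2_IT	hippocampus	-4.57	-2.12	1
Copg2_IT	caudate_putamen	-20.13	-1.23	1
Ppm1k	nucleus_accumbens	-2.05	1.30	1
Ppm1k	amygdala	-1.74	-1.62	1
Ppm1k	frontal_cortex	-2.79	-2.54	1
Ppm1k	hippocampus	-1.86	-3.12	1
Ppm1k	caudate_putamen	-2.39	-2.49	1
Snx10	nucleus_accumbens	1.67	-1.16	1
Snx10	amygdala	2.18	1.68	1
Snx10	frontal_cortex	1.94	1.15	1
Snx10	hippocampus	1.69	2.42	1
Snx10	caudate_putamen	2.02	1.64	1
Zfp212	nucleus_accumbens	1.30	1.54	1
Zfp212	amygdala	1.22	-1.04	1
Zfp212	frontal_cortex	1.21	1.19	1
Zfp212	hippocampus	1.28	1.58	1
Zfp212	caudate_putamen	1.43	1.86	1
Akr1b1	nucleus_accumbens	1.22	1.13	1
Akr1b1	amygdala	1.12	1.30	1
Akr1b1	frontal_cortex	1.27	1.58	1
Akr1b1	hippocampus	1.16	1.06	1
Akr1b1	caudate_putamen	1.25	1.15	1
Dgki	nucleus_accumbens	1.23	2.72	1
Dgki	amygdala	1.13	-1.26	1
Dgki	frontal_cortex	1.17	-2.97	1
Dgki	hippocampus	1.26	1.11	1
Dgki	caudate_putamen	1.25	-1.71	1
Pdia4	nucleus_accumbens	1.24	1.57	1
Pdia4	amygdala	1.34	-1.01	1
Pdia4	frontal_cortex	1.14	1.05	0
Pdia4	caudate_putamen	1.36	-1.13	1
Snca	frontal_cortex	-1.11	-1.22	1
Snca	hippocampus	1.07	1.05	0
Snca	caudate_putamen	-1.12	-1.09	1
Npy	frontal_cortex	-1.11	1.01	0
Npy	caudate_putamen	-1.08	-1.20	0
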