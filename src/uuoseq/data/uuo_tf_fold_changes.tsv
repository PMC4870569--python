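# Up-regulated transcription factors / transcriptional regulators in the UUO
# renal-fibrosis RNA-seq cohort, as published: linear fold change, log2 fold
# change and p-value for 2-day and 8-day post-ligation vs sham-operated.
# NA marks genes not statistically significant in the 8-day comparison.
gene	fold_2d	log2fc_2d	p_2d	fold_8d	log2fc_8d	p_8d
Sox9	55.131	5.785	6.49E-35	50.395	5.655	8.55E-34
Creb5	13.935	3.801	4.41E-05	8.946	3.161	0.000499581
Pou1f1	13.010	3.702	0.003193411	14.020	3.809	0.002526991
Uhrf1	11.428	3.514	6.08E-16	11.529	3.527	4.94E-16
Mis18bp1	9.116	3.188	5.73E-07	4.713	2.237	0.000308533
Sox11	8.000	3.000	0.000273125	25.446	4.669	1.09E-07
E2f7	7.649	2.935	0.000566974	6.717	2.748	0.001167639
Lhx2	7.459	2.899	0.047260521	9.369	3.228	0.029423642
Foxj1	7.267	2.861	2.71E-10	35.513	5.150	2.12E-25
Relb	6.574	2.717	1.50E-11	12.314	3.622	2.78E-18
Bcl3	6.302	2.656	3.38E-11	5.658	2.500	3.64E-10
Arid5a	6.044	2.596	4.64E-09	8.662	3.115	4.59E-12
Hells	5.929	2.568	8.51E-07	4.554	2.187	2.28E-05
Brca1	5.916	2.565	2.20E-05	3.772	1.915	0.001278627
Hesx1	5.857	2.550	0.0001854	NA	NA	NA
Fosl1	5.727	2.518	9.26E-05	6.357	2.668	3.71E-05
Foxm1	5.645	2.497	9.10E-08	8.384	3.068	1.16E-12
Maff	5.530	2.467	5.69E-09	18.200	4.186	1.06E-18
Runx1	5.072	2.343	1.42E-07	7.784	2.961	9.10E-07
Cdca7	5.071	2.342	7.62E-05	3.619	1.856	0.002473687
Asf1b	4.608	2.204	0.000360743	14.394	3.847	2.99E-06
Batf	4.413	2.142	0.005937201	21.757	4.443	9.04E-17
Egr2	4.089	2.032	3.81E-05	3.130	1.646	1.30E-05
Atf5	3.976	1.991	1.61E-07	4.047	2.017	9.87E-08
Sbno2	3.914	1.969	1.92E-07	3.544	1.825	0.001291195
Etv4	3.444	1.784	0.001644233	3.173	1.666	0.000280941
Arntl2	3.220	1.687	0.004706731	5.134	2.360	9.80E-05
Fosl2	3.200	1.678	1.04E-05	5.219	2.384	7.08E-10
Ciita	2.933	1.552	0.000500544	6.066	2.601	1.23E-08
Zfp182	2.735	1.452	0.001031867	NA	NA	NA
Elf3	2.734	1.451	0.000111241	4.097	2.035	8.19E-08
Sox4	2.553	1.352	0.000870541	5.374	2.426	5.02E-09
Ezh2	2.330	1.220	0.006650586	2.018	1.013	0.023999984
Ifi205	2.313	1.210	0.003867694	12.666	3.663	2.19E-16
Bex1	2.303	1.203	0.019004634	2.199	1.137	0.026564847
Ikzf4	2.285	1.192	0.018368417	NA	NA	NA
E2f1	2.280	1.189	0.004909231	1.891	0.919	0.029286962
Chaf1a	2.210	1.144	0.021923246	NA	NA	NA
Rbpms	2.105	1.074	0.003833858	2.414	1.272	0.000631062
Hmgb2	2.063	1.045	0.005585089	2.762	1.466	0.000108467
Tgif1	2.038	1.027	0.006779508	3.099	1.632	1.95E-05
Zfp57	1.895	0.922	0.016739514	2.943	1.557	0.002821029
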