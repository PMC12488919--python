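# Worked-example table of 17 genes oppositely regulated by exposure in the two sexes:
# group-mean relative expression +/- SD and Student-t p, females (BPA vs control,
# n=10 vs 5) and males (BPA vs control, n=6 vs 3).
gene	f_mean_bpa	f_sd_bpa	f_mean_ctrl	f_sd_ctrl	f_p	m_mean_bpa	m_sd_bpa	m_mean_ctrl	m_sd_ctrl	m_p
Znrf3	6.60	0.3	6.92	0.1	0.021	6.64	0.1	6.19	0.2	0.0028
Phb2	1.84	1.5	3.69	0.9	0.026	11.9	0.1	11.5	0.3	0.028
Fto	6.18	0.2	6.70	0.4	0.0048	5.00	0.4	4.04	0.3	0.011
Nlrc3	6.71	0.3	7.07	0.2	0.018	6.77	0.2	6.19	0.4	0.023
Trbv13-2	6.06	0.3	6.40	0.3	0.048	5.75	0.3	5.24	0.2	0.020
Thrap3	3.13	0.5	3.76	0.1	0.014	5.63	0.2	4.55	0.1	0.00015
Ptdss1	8.27	0.1	8.48	0.2	0.012	6.16	0.2	5.24	0.6	0.0285
Lpcat3	7.39	0.1	7.58	0.1	0.029	6.78	0.3	6.08	0.4	0.020
Becn1	5.79	0.4	6.29	0.1	0.019	5.11	0.2	4.20	0.2	0.00074
Rnf111	5.84	0.3	6.30	0.4	0.022	7.41	0.2	6.90	0.2	0.0064
Rnf144b	3.79	0.4	4.44	0.3	0.011	8.37	0.1	8.24	0.1	0.016
Copb1	8.56	0.2	8.93	0.2	0.0021	5.67	0.1	5.03	0.2	0.00094
Osbpl2	5.44	0.3	5.86	0.2	0.016	5.18	0.5	3.80	0.4	0.0048
Stx16	6.19	0.3	6.62	0.3	0.013	4.66	0.6	3.51	0.2	0.015
Ankrd17	5.69	0.2	6.01	0.2	0.013	4.42	0.4	3.20	0.6	0.0057
Eif4h	5.30	0.4	5.77	0.2	0.036	5.36	0.3	3.85	0.8	0.0041
Tfcp2	4.88	0.3	5.48	0.4	0.0071	3.56	0.7	2.21	0.5	0.021
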