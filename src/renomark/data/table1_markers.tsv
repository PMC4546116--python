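tissue	timepoint_months	activity_MBq	gene	log2_ratio	category	protein_flag
cortex	4	90	Bcat1	0.65	kidney_injury	0
cortex	4	150	Bcat1	0.63	kidney_injury	0
cortex	4	60	Egr1	1.2	kidney_injury	0
cortex	4	90	Egr1	1.3	kidney_injury	0
cortex	4	150	Egr1	1.2	kidney_injury	0
cortex	4	150	Gdf15	0.72	kidney_injury	0
cortex	4	150	Hspa1a	0.80	kidney_injury	0
cortex	4	150	Lcn2	1.0	kidney_injury	0
cortex	4	150	Mmp2	0.83	kidney_injury	1
cortex	4	90	Cdkn1a	1.2	kidney_injury_and_radiation	1
cortex	4	120	Cdkn1a	1.49	kidney_injury_and_radiation	1
cortex	4	150	Cdkn1a	2.0	kidney_injury_and_radiation	1
cortex	4	150	Ccng1	0.67	radiation	0
cortex	4	150	Gadd45g	1.5	radiation	0
cortex	4	150	Trp53inp1	0.70	radiation	0
cortex	8	150	Akap12	0.63	kidney_injury	0
cortex	8	150	Anxa3	0.88	kidney_injury	1
cortex	8	150	Col3a1	0.65	kidney_injury	0
cortex	8	150	Col4a1	0.81	kidney_injury	0
cortex	8	150	Cxcl1	1.7	kidney_injury	0
cortex	8	150	Cyr61	0.97	kidney_injury	0
cortex	8	150	Egr1	1.7	kidney_injury	0
cortex	8	120	Gdf15	0.97	kidney_injury	0
cortex	8	150	Gdf15	1.4	kidney_injury	0
cortex	8	150	Havcr1	1.6	kidney_injury	0
cortex	8	90	Hspa1a	0.61	kidney_injury	0
cortex	8	150	Icam1	0.87	kidney_injury	1
cortex	8	120	Lcn2	1.8	kidney_injury	0
cortex	8	150	Lcn2	2.0	kidney_injury	0
cortex	8	150	Lgals3	0.94	kidney_injury	0
cortex	8	120	Mmp2	1.3	kidney_injury	1
cortex	8	150	Mmp2	1.5	kidney_injury	1
cortex	8	120	S100a6	1.3	kidney_injury	0
cortex	8	150	S100a6	0.83	kidney_injury	0
cortex	8	150	Tnfrsf12a	1.2	kidney_injury	0
cortex	8	150	Vcam1	1.6	kidney_injury	0
cortex	8	90	Acta2	0.76	kidney_injury_and_radiation	0
cortex	8	150	Acta2	0.82	kidney_injury_and_radiation	0
cortex	8	60	Cdkn1a	0.87	kidney_injury_and_radiation	1
cortex	8	90	Cdkn1a	1.1	kidney_injury_and_radiation	1
cortex	8	120	Cdkn1a	1.5	kidney_injury_and_radiation	1
cortex	8	150	Cdkn1a	1.8	kidney_injury_and_radiation	1
cortex	8	150	Fos	1.0	kidney_injury_and_radiation	1
cortex	8	90	Ccng1	0.74	radiation	0
cortex	8	150	Ccng1	0.93	radiation	0
cortex	8	150	Cx3cl1	0.70	radiation	0
cortex	8	30	Cxcl12	0.77	radiation	0
cortex	8	30	Gadd45g	0.87	radiation	0
cortex	8	30	Gjb2	-0.97	radiation	0
cortex	8	90	Gjb2	-0.86	radiation	0
cortex	12	30	Acox1	-0.73	kidney_injury	0
cortex	12	60	Acox1	-0.78	kidney_injury	0
cortex	12	90	Acox1	-0.72	kidney_injury	0
cortex	12	90	Anxa2	0.77	kidney_injury	0
cortex	12	120	Anxa2	0.72	kidney_injury	0
cortex	12	90	Anxa3	0.64	kidney_injury	1
cortex	12	90	Bcat1	0.75	kidney_injury	0
cortex	12	90	Col4a1	0.68	kidney_injury	0
cortex	12	150	Cxcl1	2.7	kidney_injury	0
cortex	12	120	Egr1	0.65	kidney_injury	0
cortex	12	90	Gdf15	0.70	kidney_injury	0
cortex	12	120	Gdf15	0.59	kidney_injury	0
cortex	12	30	Hspa1a	0.66	kidney_injury	0
cortex	12	90	Lcn2	0.80	kidney_injury	0
cortex	12	120	Lcn2	0.76	kidney_injury	0
cortex	12	150	Lcn2	3.6	kidney_injury	0
cortex	12	90	Mmp2	0.84	kidney_injury	1
cortex	12	120	Mmp2	0.93	kidney_injury	1
cortex	12	30	Mt1	-0.64	kidney_injury	0
cortex	12	60	Mt1	-0.70	kidney_injury	0
cortex	12	30	S100a6	1.3	kidney_injury	0
cortex	12	60	S100a6	0.86	kidney_injury	0
cortex	12	90	S100a6	1.2	kidney_injury	0
cortex	12	120	S100a6	1.0	kidney_injury	0
cortex	12	90	Vcam1	0.88	kidney_injury	0
cortex	12	120	Vcam1	0.66	kidney_injury	0
cortex	12	150	Vcam1	2.1	kidney_injury	0
cortex	12	30	Acta2	1.1	kidney_injury_and_radiation	0
cortex	12	60	Acta2	0.94	kidney_injury_and_radiation	0
cortex	12	90	Acta2	1.1	kidney_injury_and_radiation	0
cortex	12	30	Cdkn1a	1.3	kidney_injury_and_radiation	1
cortex	12	60	Cdkn1a	1.0	kidney_injury_and_radiation	1
cortex	12	90	Cdkn1a	1.6	kidney_injury_and_radiation	1
cortex	12	120	Cdkn1a	1.4	kidney_injury_and_radiation	1
cortex	12	150	Cdkn1a	2.0	kidney_injury_and_radiation	1
cortex	12	90	Ccnd1	0.65	radiation	1
cortex	12	120	Ccnd1	0.61	radiation	1
cortex	12	60	Gadd45g	-0.61	radiation	0
cortex	12	30	Gja1	0.81	radiation	0
cortex	12	120	Gja1	0.79	radiation	0
cortex	12	30	Gjb2	-0.59	radiation	0
cortex	12	120	Lep	0.83	radiation	0
cortex	12	60	Tnfrsf21	-0.91	radiation	0
cortex	12	120	Tnfrsf21	-1.0	radiation	0
medulla	4	30	Cyr61	0.75	kidney_injury	0
medulla	4	30	Egr1	1.7	kidney_injury	0
medulla	4	60	Egr1	1.1	kidney_injury	0
medulla	4	90	Egr1	1.1	kidney_injury	0
medulla	4	150	Egr1	1.2	kidney_injury	0
medulla	4	150	Igfbp3	-0.70	kidney_injury	0
medulla	4	150	Mmp2	1.0	kidney_injury	1
medulla	4	60	S100a6	-0.73	kidney_injury	0
medulla	4	60	Cdkn1a	0.69	kidney_injury_and_radiation	1
medulla	4	90	Cdkn1a	1.1	kidney_injury_and_radiation	1
medulla	4	120	Cdkn1a	1.2	kidney_injury_and_radiation	1
medulla	4	150	Cdkn1a	1.8	kidney_injury_and_radiation	1
medulla	4	30	Fos	0.91	kidney_injury_and_radiation	1
medulla	4	60	Cxcl12	-0.99	radiation	0
medulla	4	60	Gadd45g	-0.69	radiation	0
medulla	4	120	Gadd45g	-0.64	radiation	0
medulla	4	150	Gadd45g	1.2	radiation	0
medulla	4	60	Tnfrsf21	-0.81	radiation	0
medulla	8	150	Anxa2	0.62	kidney_injury	0
medulla	8	150	Anxa3	0.78	kidney_injury	1
medulla	8	150	Col3a1	0.72	kidney_injury	0
medulla	8	150	Col4a1	0.66	kidney_injury	0
medulla	8	150	Cxcl1	1.4	kidney_injury	0
medulla	8	150	Cyr61	0.71	kidney_injury	0
medulla	8	60	Egr1	0.79	kidney_injury	0
medulla	8	90	Egr1	1.3	kidney_injury	0
medulla	8	150	Egr1	1.8	kidney_injury	0
medulla	8	150	Gdf15	1.2	kidney_injury	0
medulla	8	120	Havcr1	1.6	kidney_injury	0
medulla	8	150	Havcr1	1.3	kidney_injury	0
medulla	8	60	Hspa1a	0.79	kidney_injury	0
medulla	8	90	Hspa1a	1.0	kidney_injury	0
medulla	8	150	Igfbp3	-0.77	kidney_injury	0
medulla	8	60	Lcn2	0.86	kidney_injury	0
medulla	8	120	Lcn2	1.6	kidney_injury	0
medulla	8	150	Lcn2	1.9	kidney_injury	0
medulla	8	150	Lgals3	0.87	kidney_injury	0
medulla	8	120	Mmp2	1.1	kidney_injury	1
medulla	8	150	Mmp2	1.0	kidney_injury	1
medulla	8	60	Mt1	-0.70	kidney_injury	0
medulla	8	30	S100a6	-0.72	kidney_injury	0
medulla	8	60	S100a6	1.0	kidney_injury	0
medulla	8	90	S100a6	1.0	kidney_injury	0
medulla	8	150	S100a6	0.97	kidney_injury	0
medulla	8	150	Tnfrsf12a	1.1	kidney_injury	0
medulla	8	150	Vcam1	1.2	kidney_injury	0
medulla	8	90	Acta2	0.75	kidney_injury_and_radiation	0
medulla	8	150	Acta2	0.76	kidney_injury_and_radiation	0
medulla	8	60	Cdkn1a	1.0	kidney_injury_and_radiation	1
medulla	8	90	Cdkn1a	1.2	kidney_injury_and_radiation	1
medulla	8	120	Cdkn1a	1.5	kidney_injury_and_radiation	1
medulla	8	150	Cdkn1a	1.7	kidney_injury_and_radiation	1
medulla	8	90	Fos	0.62	kidney_injury_and_radiation	1
medulla	8	150	Fos	1.2	kidney_injury_and_radiation	1
medulla	8	30	Cxcl9	0.78	radiation	0
medulla	8	150	Cxcl9	0.72	radiation	0
medulla	8	30	Pcna	0.62	radiation	1
medulla	8	30	Tnfrsf21	-1.0	radiation	0
medulla	8	60	Tnfrsf21	-1.1	radiation	0
medulla	12	120	Acox1	-0.59	kidney_injury	0
medulla	12	120	Afm	-0.68	kidney_injury	0
medulla	12	120	Col4a1	0.74	kidney_injury	0
medulla	12	120	Lcn2	0.91	kidney_injury	0
medulla	12	150	Lcn2	3.2	kidney_injury	0
medulla	12	90	Mmp2	0.66	kidney_injury	1
medulla	12	120	Mmp2	0.70	kidney_injury	1
medulla	12	30	Acta2	0.91	kidney_injury_and_radiation	0
medulla	12	60	Acta2	0.80	kidney_injury_and_radiation	0
medulla	12	90	Acta2	1.1	kidney_injury_and_radiation	0
medulla	12	30	Cdkn1a	1.3	kidney_injury_and_radiation	1
medulla	12	60	Cdkn1a	1.1	kidney_injury_and_radiation	1
medulla	12	90	Cdkn1a	1.4	kidney_injury_and_radiation	1
medulla	12	120	Cdkn1a	1.1	kidney_injury_and_radiation	1
medulla	12	150	Cdkn1a	1.5	kidney_injury_and_radiation	1
medulla	12	120	Ccnd1	0.58	radiation	1
medulla	12	120	Ccng1	0.63	radiation	0
medulla	12	30	Gjb2	-0.75	radiation	0
medulla	12	120	Hspe1	-0.63	radiation	0
medulla	12	60	Tnfrsf21	-0.93	radiation	0
medulla	12	90	Tnfrsf21	-0.64	radiation	0
medulla	12	150	Tnfrsf21	-1.5	radiation	0
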