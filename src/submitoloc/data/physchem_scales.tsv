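# 31 per-residue physico-chemical scales (AAindex-style). Each row is one
# scale; columns follow the alphabetical one-letter residue order. The set is
# a curated convention covering hydrophobicity, size, polarity, flexibility,
# structural propensity, charge and atomic-composition descriptors; it is
# overridable via configuration. Row order fixes feature order.
scale	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydropathy_kyte_doolittle	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hydrophilicity_hopp_woods	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
hydrophobicity_eisenberg	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophobicity_fauchere_pliska	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
buried_tendency_janin	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
transmembrane_tendency	0.38	-0.30	-3.27	-2.90	1.98	-0.19	-1.44	1.97	-3.46	1.82	1.40	-1.62	-1.44	-1.84	-2.57	-0.53	-0.32	1.46	1.53	0.49
bulkiness_zimmerman	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
polarity_grantham	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
polarity_zimmerman	0.00	1.48	49.70	49.90	0.35	0.00	51.60	0.13	49.50	0.13	1.43	3.38	1.58	3.53	52.00	1.67	1.66	0.13	2.10	1.61
flexibility_bhaskaran	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
residue_mass	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.10	97.12	128.13	156.19	87.08	101.10	99.13	186.21	163.18
residue_volume_chothia	88.6	108.5	111.1	138.4	189.9	60.1	153.2	166.7	168.6	166.7	162.9	114.1	112.7	143.8	173.4	89.0	116.1	140.0	227.8	193.6
accessible_surface_area	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
isoelectric_point	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
refractivity	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
relative_mutability	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41
helix_propensity_chou_fasman	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
sheet_propensity_chou_fasman	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
turn_propensity_chou_fasman	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
net_charge_ph7	0	0	-1	-1	0	0	0.1	0	1	0	0	0	0	0	1	0	0	0	0	0
aromaticity	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0	1	1
aliphaticity	1	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0	1	0	0
sidechain_hbond_donors	0	1	0	0	0	0	1	0	3	0	0	2	0	2	5	1	1	0	1	1
sidechain_hbond_acceptors	0	0	4	4	0	0	1	0	0	0	0	2	0	2	0	2	2	0	0	1
sidechain_nitrogens	0	0	0	0	0	0	2	0	1	0	0	1	0	1	3	0	0	0	1	0
sidechain_oxygens	0	0	2	2	0	0	0	0	0	0	0	1	0	1	0	1	1	0	0	1
sidechain_sulfurs	0	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
sidechain_carbons	1	1	2	3	7	0	4	4	4	4	3	2	3	3	4	1	2	3	9	7
steric_parameter_charton	0.52	0.62	0.76	0.68	0.70	0.00	0.70	1.02	0.68	0.98	0.78	0.76	0.64	0.68	0.68	0.53	0.70	0.76	0.70	0.70
sidechain_pka	0	8.18	3.65	4.25	0	0	6.00	0	10.53	0	0	0	0	0	12.48	0	0	0	0	10.07
heat_capacity_hutchens	29.22	50.70	37.09	41.84	48.52	23.71	59.64	45.00	57.10	48.03	69.32	38.30	36.13	44.02	26.37	32.40	35.20	40.35	56.92	51.73
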