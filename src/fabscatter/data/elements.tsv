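# X-ray atomic scattering factor coefficients (Cromer-Mann 4-Gaussian
# parameterization, International Tables for Crystallography Vol. C, Table
# 6.1.1.4) and per-element displaced solvent volumes (A^3, Fraser et al.
# 1978, as used for excluded-volume corrections in solution scattering).
# f(q) = sum_k a_k exp(-b_k (q/4pi)^2) + c
# element	Z	a1	a2	a3	a4	b1	b2	b3	b4	c	v_displaced
H	1	0.493002	0.322912	0.140191	0.040810	10.5109	26.1257	3.14236	57.7997	0.003038	5.15
C	6	2.31000	1.02000	1.58860	0.865000	20.8439	10.2075	0.568700	51.6512	0.215600	16.44
N	7	12.2126	3.13220	2.01250	1.16630	0.005700	9.89330	28.9975	0.582600	-11.529	2.49
O	8	3.04850	2.28680	1.54630	0.867000	13.2771	5.70110	0.323900	32.9089	0.250800	9.13
P	15	6.43450	4.17910	1.78000	1.49080	1.90670	27.1570	0.526000	68.1645	1.11490	5.73
S	16	6.90530	5.20340	1.43790	1.58630	1.46790	22.2151	0.253600	56.1720	0.866900	19.86
NA	11	4.76260	3.17360	1.26740	1.11280	3.28500	8.84220	0.313600	129.424	0.676000	16.90
CL	17	11.4604	7.19640	6.25560	1.64550	0.010400	1.16620	18.5194	47.7784	-9.5574	28.80
K	19	8.21860	7.43980	1.05190	0.865900	12.7949	0.774800	213.187	41.6841	1.42280	30.30
CA	20	8.62660	7.38730	1.58990	1.02110	10.4421	0.659900	85.7484	178.437	1.37510	31.90
FE	26	11.7695	7.35730	3.52220	2.30450	4.76110	0.307200	15.3535	76.8805	1.03690	7.99
ZN	30	14.0743	7.03180	5.16520	2.41000	3.26550	0.233300	10.3163	58.7097	1.30410	9.85
SE	34	17.0006	5.81960	3.97310	4.35430	2.40980	0.272600	15.2372	43.8163	2.84090	28.73
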