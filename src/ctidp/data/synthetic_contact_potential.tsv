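# Synthetic residue-pair contact-potential table (dimensionless).
# SYNTHETIC stand-in for a knowledge-based statistical potential:
# e(a,b) = -0.15*(h_a + h_b) - 2.0 if opposite charges, + 1.0 if like charges,
# with h the Kyte-Doolittle index. Attractive pairs are negative. Any symmetric
# 20x20 table in this format can be substituted via the loader.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.540	-0.645	0.255	0.255	-0.690	-0.210	0.210	-0.945	0.315	-0.840	-0.555	0.255	-0.030	0.255	0.405	-0.150	-0.165	-0.900	-0.135	-0.075
C	-0.645	-0.750	0.150	0.150	-0.795	-0.315	0.105	-1.050	0.210	-0.945	-0.660	0.150	-0.135	0.150	0.300	-0.255	-0.270	-1.005	-0.240	-0.180
D	0.255	0.150	2.050	2.050	0.105	0.585	1.005	-0.150	-0.890	-0.045	0.240	1.050	0.765	1.050	-0.800	0.645	0.630	-0.105	0.660	0.720
E	0.255	0.150	2.050	2.050	0.105	0.585	1.005	-0.150	-0.890	-0.045	0.240	1.050	0.765	1.050	-0.800	0.645	0.630	-0.105	0.660	0.720
F	-0.690	-0.795	0.105	0.105	-0.840	-0.360	0.060	-1.095	0.165	-0.990	-0.705	0.105	-0.180	0.105	0.255	-0.300	-0.315	-1.050	-0.285	-0.225
G	-0.210	-0.315	0.585	0.585	-0.360	0.120	0.540	-0.615	0.645	-0.510	-0.225	0.585	0.300	0.585	0.735	0.180	0.165	-0.570	0.195	0.255
H	0.210	0.105	1.005	1.005	0.060	0.540	0.960	-0.195	1.065	-0.090	0.195	1.005	0.720	1.005	1.155	0.600	0.585	-0.150	0.615	0.675
I	-0.945	-1.050	-0.150	-0.150	-1.095	-0.615	-0.195	-1.350	-0.090	-1.245	-0.960	-0.150	-0.435	-0.150	-0.000	-0.555	-0.570	-1.305	-0.540	-0.480
K	0.315	0.210	-0.890	-0.890	0.165	0.645	1.065	-0.090	2.170	0.015	0.300	1.110	0.825	1.110	2.260	0.705	0.690	-0.045	0.720	0.780
L	-0.840	-0.945	-0.045	-0.045	-0.990	-0.510	-0.090	-1.245	0.015	-1.140	-0.855	-0.045	-0.330	-0.045	0.105	-0.450	-0.465	-1.200	-0.435	-0.375
M	-0.555	-0.660	0.240	0.240	-0.705	-0.225	0.195	-0.960	0.300	-0.855	-0.570	0.240	-0.045	0.240	0.390	-0.165	-0.180	-0.915	-0.150	-0.090
N	0.255	0.150	1.050	1.050	0.105	0.585	1.005	-0.150	1.110	-0.045	0.240	1.050	0.765	1.050	1.200	0.645	0.630	-0.105	0.660	0.720
P	-0.030	-0.135	0.765	0.765	-0.180	0.300	0.720	-0.435	0.825	-0.330	-0.045	0.765	0.480	0.765	0.915	0.360	0.345	-0.390	0.375	0.435
Q	0.255	0.150	1.050	1.050	0.105	0.585	1.005	-0.150	1.110	-0.045	0.240	1.050	0.765	1.050	1.200	0.645	0.630	-0.105	0.660	0.720
R	0.405	0.300	-0.800	-0.800	0.255	0.735	1.155	-0.000	2.260	0.105	0.390	1.200	0.915	1.200	2.350	0.795	0.780	0.045	0.810	0.870
S	-0.150	-0.255	0.645	0.645	-0.300	0.180	0.600	-0.555	0.705	-0.450	-0.165	0.645	0.360	0.645	0.795	0.240	0.225	-0.510	0.255	0.315
T	-0.165	-0.270	0.630	0.630	-0.315	0.165	0.585	-0.570	0.690	-0.465	-0.180	0.630	0.345	0.630	0.780	0.225	0.210	-0.525	0.240	0.300
V	-0.900	-1.005	-0.105	-0.105	-1.050	-0.570	-0.150	-1.305	-0.045	-1.200	-0.915	-0.105	-0.390	-0.105	0.045	-0.510	-0.525	-1.260	-0.495	-0.435
W	-0.135	-0.240	0.660	0.660	-0.285	0.195	0.615	-0.540	0.720	-0.435	-0.150	0.660	0.375	0.660	0.810	0.255	0.240	-0.495	0.270	0.330
Y	-0.075	-0.180	0.720	0.720	-0.225	0.255	0.675	-0.480	0.780	-0.375	-0.090	0.720	0.435	0.720	0.870	0.315	0.300	-0.435	0.330	0.390
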