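# AutoDock 4.0 atom-type parameters (Rii: sum of vdW radii of two like
# atoms, Å; epsii: vdW well depth, kcal/mol; vol: atomic fragmental
# volume, Å³; solpar: atomic solvation parameter; hbond: 0 none,
# D donor-hydrogen, A1 N-acceptor, A2 O/S-acceptor; Rij_hb/epsij_hb:
# 12-10 hydrogen-bond equilibrium distance (Å) and well depth (kcal/mol)
# carried by the acceptor type).
atom_type	Rii	epsii	vol	solpar	hbond	Rij_hb	epsij_hb
H	2.00	0.020	0.0000	0.00051	0	0.0	0.0
HD	2.00	0.020	0.0000	0.00051	D	0.0	0.0
HS	2.00	0.020	0.0000	0.00051	D	0.0	0.0
C	4.00	0.150	33.5103	-0.00143	0	0.0	0.0
A	4.00	0.150	33.5103	-0.00052	0	0.0	0.0
N	3.50	0.160	22.4493	-0.00162	0	0.0	0.0
NA	3.50	0.160	22.4493	-0.00162	A1	1.9	5.0
NS	3.50	0.160	22.4493	-0.00162	A1	1.9	5.0
OA	3.20	0.200	17.1573	-0.00251	A2	1.9	5.0
OS	3.20	0.200	17.1573	-0.00251	A2	1.9	5.0
F	3.09	0.080	15.4480	-0.00110	0	0.0	0.0
Mg	1.30	0.875	1.5600	-0.00110	0	0.0	0.0
P	4.20	0.200	38.7924	-0.00110	0	0.0	0.0
SA	4.00	0.200	33.5103	-0.00214	A2	2.5	1.0
S	4.00	0.200	33.5103	-0.00214	0	0.0	0.0
Cl	4.09	0.276	35.8235	-0.00110	0	0.0	0.0
Ca	1.98	0.550	2.7700	-0.00110	0	0.0	0.0
Mn	1.30	0.875	2.1400	-0.00110	0	0.0	0.0
Fe	1.30	0.010	1.8400	-0.00110	0	0.0	0.0
Zn	1.48	0.550	1.7000	-0.00110	0	0.0	0.0
Br	4.33	0.389	42.5661	-0.00110	0	0.0	0.0
I	4.72	0.550	55.0585	-0.00110	0	0.0	0.0
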