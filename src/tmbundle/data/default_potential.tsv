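# default coarse-grained contact table (hydropathy-derived stand-in)
# cutoff=12.0 A, charge wells: epsilon=300 kB*K at sigma=4.0 A (Gaussian, width 1.0 A)
aa_i	aa_j	epsilon	sigma
A	A	149.550000	5.0
A	C	165.611111	5.0
A	D	27.944444	5.0
A	E	27.944444	5.0
A	F	172.494444	5.0
A	G	99.072222	5.0
A	H	34.827778	5.0
A	I	211.500000	5.0
A	K	18.766667	5.0
A	L	195.438889	5.0
A	M	151.844444	5.0
A	N	27.944444	5.0
A	P	71.538889	5.0
A	Q	27.944444	5.0
A	R	5.000000	5.0
A	S	89.894444	5.0
A	T	92.188889	5.0
A	V	204.616667	5.0
A	W	87.600000	5.0
A	Y	78.422222	5.0
C	C	183.456790	5.0
C	D	30.493827	5.0
C	E	30.493827	5.0
C	F	191.104938	5.0
C	G	109.524691	5.0
C	H	38.141975	5.0
C	I	234.444444	5.0
C	K	20.296296	5.0
C	L	216.598765	5.0
C	M	168.160494	5.0
C	N	30.493827	5.0
C	P	78.932099	5.0
C	Q	30.493827	5.0
C	R	5.000000	5.0
C	S	99.327160	5.0
C	T	101.876543	5.0
C	V	226.796296	5.0
C	W	96.777778	5.0
C	Y	86.580247	5.0
D	D	8.641975	5.0
D	E	8.641975	5.0
D	F	31.586420	5.0
D	G	19.932099	5.0
D	H	9.734568	5.0
D	I	37.777778	5.0
D	K	7.185185	5.0
D	L	35.228395	5.0
D	M	28.308642	5.0
D	N	8.641975	5.0
D	P	15.561728	5.0
D	Q	8.641975	5.0
D	R	5.000000	5.0
D	S	18.475309	5.0
D	T	18.839506	5.0
D	V	36.685185	5.0
D	W	18.111111	5.0
D	Y	16.654321	5.0
E	E	8.641975	5.0
E	F	31.586420	5.0
E	G	19.932099	5.0
E	H	9.734568	5.0
E	I	37.777778	5.0
E	K	7.185185	5.0
E	L	35.228395	5.0
E	M	28.308642	5.0
E	N	8.641975	5.0
E	P	15.561728	5.0
E	Q	8.641975	5.0
E	R	5.000000	5.0
E	S	18.475309	5.0
E	T	18.839506	5.0
E	V	36.685185	5.0
E	W	18.111111	5.0
E	Y	16.654321	5.0
F	F	199.080864	5.0
F	G	114.004321	5.0
F	H	39.562346	5.0
F	I	244.277778	5.0
F	K	20.951852	5.0
F	L	225.667284	5.0
F	M	175.153086	5.0
F	N	31.586420	5.0
F	P	82.100617	5.0
F	Q	31.586420	5.0
F	R	5.000000	5.0
F	S	103.369753	5.0
F	T	106.028395	5.0
F	V	236.301852	5.0
F	W	100.711111	5.0
F	Y	90.076543	5.0
G	G	66.221605	5.0
G	H	24.411728	5.0
G	I	139.388889	5.0
G	K	13.959259	5.0
G	L	128.936420	5.0
G	M	100.565432	5.0
G	N	19.932099	5.0
G	P	48.303086	5.0
G	Q	19.932099	5.0
G	R	5.000000	5.0
G	S	60.248765	5.0
G	T	61.741975	5.0
G	V	134.909259	5.0
G	W	58.755556	5.0
G	Y	52.782716	5.0
H	H	11.154938	5.0
H	I	47.611111	5.0
H	K	7.840741	5.0
H	L	44.296914	5.0
H	M	35.301235	5.0
H	N	9.734568	5.0
H	P	18.730247	5.0
H	Q	9.734568	5.0
H	R	5.000000	5.0
H	S	22.517901	5.0
H	T	22.991358	5.0
H	V	46.190741	5.0
H	W	22.044444	5.0
H	Y	20.150617	5.0
I	I	300.000000	5.0
I	K	24.666667	5.0
I	L	277.055556	5.0
I	M	214.777778	5.0
I	N	37.777778	5.0
I	P	100.055556	5.0
I	Q	37.777778	5.0
I	R	5.000000	5.0
I	S	126.277778	5.0
I	T	129.555556	5.0
I	V	290.166667	5.0
I	W	123.000000	5.0
I	Y	109.888889	5.0
K	K	6.311111	5.0
K	L	23.137037	5.0
K	M	18.985185	5.0
K	N	7.185185	5.0
K	P	11.337037	5.0
K	Q	7.185185	5.0
K	R	5.000000	5.0
K	S	13.085185	5.0
K	T	13.303704	5.0
K	V	24.011111	5.0
K	W	12.866667	5.0
K	Y	11.992593	5.0
L	L	255.895679	5.0
L	M	198.461728	5.0
L	N	35.228395	5.0
L	P	92.662346	5.0
L	Q	35.228395	5.0
L	R	5.000000	5.0
L	S	116.845062	5.0
L	T	119.867901	5.0
L	V	267.987037	5.0
L	W	113.822222	5.0
L	Y	101.730864	5.0
M	M	154.175309	5.0
M	N	28.308642	5.0
M	P	72.595062	5.0
M	Q	28.308642	5.0
M	R	5.000000	5.0
M	S	91.241975	5.0
M	T	93.572840	5.0
M	V	207.785185	5.0
M	W	88.911111	5.0
M	Y	79.587654	5.0
N	N	8.641975	5.0
N	P	15.561728	5.0
N	Q	8.641975	5.0
N	R	5.000000	5.0
N	S	18.475309	5.0
N	T	18.839506	5.0
N	V	36.685185	5.0
N	W	18.111111	5.0
N	Y	16.654321	5.0
P	P	35.629012	5.0
P	Q	15.561728	5.0
P	R	5.000000	5.0
P	S	44.078395	5.0
P	T	45.134568	5.0
P	V	96.887037	5.0
P	W	43.022222	5.0
P	Y	38.797531	5.0
Q	Q	8.641975	5.0
Q	R	5.000000	5.0
Q	S	18.475309	5.0
Q	T	18.839506	5.0
Q	V	36.685185	5.0
Q	W	18.111111	5.0
Q	Y	16.654321	5.0
R	R	5.000000	5.0
R	S	5.000000	5.0
R	T	5.000000	5.0
R	V	5.000000	5.0
R	W	5.000000	5.0
R	Y	5.000000	5.0
S	S	54.858642	5.0
S	T	56.206173	5.0
S	V	122.235185	5.0
S	W	53.511111	5.0
S	Y	48.120988	5.0
T	T	57.590123	5.0
T	V	125.403704	5.0
T	W	54.822222	5.0
T	Y	49.286420	5.0
V	V	280.661111	5.0
V	W	119.066667	5.0
V	Y	106.392593	5.0
W	W	52.200000	5.0
W	Y	46.955556	5.0
Y	Y	42.293827	5.0
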