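# Bundled, widely published hydrophobicity scales (two-column dialect).
# Values transcribed from the standard literature tables; the KD scale is
# the package's default "hydrophobic" reference scale.

#id: KD
#name: Kyte-Doolittle hydropathy
#category: experimental
A	1.8
R	-4.5
N	-3.5
D	-3.5
C	2.5
Q	-3.5
E	-3.5
G	-0.4
H	-3.2
I	4.5
L	3.8
K	-3.9
M	1.9
F	2.8
P	-1.6
S	-0.8
T	-0.7
W	-0.9
Y	-1.3
V	4.2

#id: EISEN
#name: Eisenberg consensus hydrophobicity
#category: calculated
A	0.62
R	-2.53
N	-0.78
D	-0.90
C	0.29
Q	-0.85
E	-0.74
G	0.48
H	-0.40
I	1.38
L	1.06
K	-1.50
M	0.64
F	1.19
P	0.12
S	-0.18
T	-0.05
W	0.81
Y	0.26
V	1.08

#id: HW
#name: Hopp-Woods hydrophilicity
#category: experimental
A	-0.5
R	3.0
N	0.2
D	3.0
C	-1.0
Q	0.2
E	3.0
G	0.0
H	-0.5
I	-1.8
L	-1.8
K	3.0
M	-1.3
F	-2.5
P	0.0
S	0.3
T	-0.4
W	-3.4
Y	-2.3
V	-1.5

#id: GES
#name: Engelman GES transfer free energy
#category: experimental
A	1.6
R	-12.3
N	-4.8
D	-9.2
C	2.0
Q	-4.1
E	-8.2
G	1.0
H	-3.0
I	3.1
L	2.8
K	-8.8
M	3.4
F	3.7
P	-0.2
S	0.6
T	1.2
W	1.9
Y	-0.7
V	2.6

#id: WWI
#name: Wimley-White interface scale
#category: experimental
A	-0.17
R	-0.81
N	-0.42
D	-1.23
C	0.24
Q	-0.58
E	-2.02
G	-0.01
H	-0.17
I	0.31
L	0.56
K	-0.99
M	0.23
F	1.13
P	-0.45
S	-0.13
T	-0.14
W	1.85
Y	0.94
V	-0.07
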