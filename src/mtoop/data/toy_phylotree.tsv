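#genome_length=16569
node	parent	variants
ROOT
H2a2a1	ROOT
L0	ROOT	m.263A>G;m.5231G>A;m.9042C>T
L0a	L0	m.200A>G
L1	ROOT	m.3666G>A;m.7055A>G
L1c	L1	m.6071T>C
L2	ROOT	m.2416T>C;m.8206G>A
L2a	L2	m.13590G>A
L3	ROOT	m.769G>A;m.1018G>A
L3e	L3	m.2352T>C
L3e1	L3e	m.6221T>C
L3e1b	L3e1	m.14869G>A
L3e1b2	L3e1b	m.5460G>A
L3e2	L3e	m.9377A>G
L3e2b	L3e2	m.4158A>G
L3e2b1	L3e2b	m.15946C>T
L3e2b1a	L3e2b1	m.16041A>G
L3e2b1a2	L3e2b1a	m.6150G>A
L4	ROOT	m.5147G>A
L5	ROOT	m.8754C>T
L6	ROOT	m.9072A>G
N	ROOT	m.8701A>G;m.9540T>C
I	N	m.10034T>C
W	N	m.11947A>G
X	N	m.6371C>T
X2	X	m.1719G>A
X2p	X2	m.12397A>G
X2p1	X2p	m.11778G>A;m.13966A>G
Q	N	m.4117T>C
Q3	Q	m.12940G>A
Q3b	Q3	m.14484T>C
R	N	m.12705C>T
J	R	m.4216T>C;m.10398A>G
T	R	m.709G>A;m.1888G>A
U	R	m.11467A>G;m.12308A>G
U3	U	m.14139A>G
U3a	U3	m.6518C>T
U3a1	U3a	m.13934C>T
U3a1a	U3a1	m.6047A>G
U3a1a1	U3a1a	m.14258G>A
U4	U	m.4646T>C
U4b	U4	m.5999T>C
U4b1	U4b	m.7705T>C
U4b1b	U4b1	m.13020T>C
U4b1b1	U4b1b	m.15693T>C
U5	U	m.3197T>C
U5a	U5	m.14793A>G
U5a1	U5a	m.15218A>G
U5a1a	U5a1	m.1700T>C
U5a1a1	U5a1a	m.5495T>C
K	U	m.1811A>G;m.9055G>A
K1	K	m.10550A>G
HV	R	m.8701A>G!;m.2259C>T
V	HV	m.4580G>A
H	HV	m.6776T>C
H1	H	m.3010G>A
H1q	H1	m.4639T>C
H1q3	H1q	m.14258G>A
H3	H	m.6253T>C
H3c	H3	m.2581A>G
H3c2	H3c	m.9947G>A
H3c2b	H3c2	m.13759G>A
H3c2b1	H3c2b	m.16093T>C
H4	H	m.3992C>T
H4a	H4	m.14582A>G
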