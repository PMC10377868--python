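property	group	residues
hydrophobicity_PRAM900101	1	R,K,E,D,Q,N
hydrophobicity_PRAM900101	2	G,A,S,T,P,H,Y
hydrophobicity_PRAM900101	3	C,L,V,I,M,F,W
hydrophobicity_ARGP820101	1	Q,S,T,N,G,D,E
hydrophobicity_ARGP820101	2	R,A,H,C,K,M,V
hydrophobicity_ARGP820101	3	L,Y,P,F,I,W
hydrophobicity_ZIMJ680101	1	Q,N,G,S,W,T,D,E,R,A
hydrophobicity_ZIMJ680101	2	H,M,C,K,V
hydrophobicity_ZIMJ680101	3	L,P,F,Y,I
hydrophobicity_PONP930101	1	K,P,D,E,S,N,Q,T
hydrophobicity_PONP930101	2	G,R,H,A
hydrophobicity_PONP930101	3	Y,M,F,W,L,C,V,I
hydrophobicity_CASG920101	1	K,D,E,Q,P,S,R,N,T,G
hydrophobicity_CASG920101	2	A,H,Y,M,L,V
hydrophobicity_CASG920101	3	F,I,W,C
hydrophobicity_ENGD860101	1	R,D,K,E,N,Q,H,Y,P
hydrophobicity_ENGD860101	2	S,G,T,A,W
hydrophobicity_ENGD860101	3	C,V,L,I,M,F
hydrophobicity_FASG890101	1	K,E,R,S,Q,D
hydrophobicity_FASG890101	2	N,T,P,G
hydrophobicity_FASG890101	3	A,Y,H,W,V,M,F,L,I,C
normwaalsvolume	1	G,A,S,T,P,D,C
normwaalsvolume	2	N,V,E,Q,I,L
normwaalsvolume	3	M,H,K,F,R,Y,W
polarity	1	L,I,F,W,C,M,V,Y
polarity	2	P,A,T,G,S
polarity	3	H,Q,R,K,N,E,D
polarizability	1	G,A,S,D,T
polarizability	2	C,P,N,V,E,Q,I,L
polarizability	3	K,M,H,F,R,Y,W
charge	1	K,R
charge	2	A,N,C,Q,G,H,I,L,M,F,P,S,T,W,Y,V
charge	3	D,E
secondarystruct	1	E,A,L,M,Q,K,R,H
secondarystruct	2	V,I,Y,C,W,F,T
secondarystruct	3	G,N,P,S,D
solventaccess	1	A,L,F,C,G,I,V,W
solventaccess	2	R,K,Q,E,N,D
solventaccess	3	M,P,S,T,H,Y
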