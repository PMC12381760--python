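# Repbase category -> RepeatMasker Type/SubType translation layer.
# Reconstructed from publicly documented RepeatMasker classification
# conventions (e.g. Gypsy -> LTR/Gypsy, Mariner/Tc1 -> DNA/TcMar,
# Helitron -> RC/Helitron); 156 source categories map onto 9 Types and
# 44 SubTypes. An empty third column maps the source at Type level only.
# Columns: source_label<TAB>type_label<TAB>subtype_label
Gypsy	LTR	Gypsy
Ty3	LTR	Gypsy
Ty3/Gypsy	LTR	Gypsy
Copia	LTR	Copia
Ty1	LTR	Copia
Ty1/Copia	LTR	Copia
BEL	LTR	Pao
Pao	LTR	Pao
Bel-Pao	LTR	Pao
DIRS	LTR	DIRS
Ngaro	LTR	Ngaro
VIPER	LTR	Ngaro
ERV1	LTR	ERV1
ERV2	LTR	ERVK
ERV3	LTR	ERVL
ERV4	LTR	ERV1
ERV	LTR	
Endogenous Retrovirus	LTR	
Lentivirus	LTR	ERV1
Retrovirus	LTR	ERV1
MaLR	LTR	ERVL
LTR Retrotransposon	LTR	
LTR	LTR	
Cassandra	LTR	Cassandra
Caulimoviridae	LTR	
L1	LINE	L1
Tx1	LINE	L1
L2	LINE	L2
L2A	LINE	L2
L2B	LINE	L2
CR1	LINE	CR1
L3/CR1	LINE	CR1
Zenon	LINE	CR1
RTE	LINE	RTE
RTEX	LINE	RTE
RTETP	LINE	RTE
BovB	LINE	RTE
R1	LINE	R1
LOA	LINE	R1
R2	LINE	R2
Hero	LINE	R2
CRE	LINE	CRE
NeSL	LINE	CRE
SLACS	LINE	CRE
CZAR	LINE	CRE
I	LINE	I
Ingi	LINE	I
Nimb	LINE	I
Outcast	LINE	I
Crack	LINE	I
Vingi	LINE	I
Jockey	LINE	Jockey
Daphne	LINE	Jockey
Kiri	LINE	Jockey
TART	LINE	Jockey
TAHRE	LINE	Jockey
HeT-A	LINE	Jockey
Rex1	LINE	Rex-Babar
Babar	LINE	Rex-Babar
Dong	LINE	Dong-R4
R4	LINE	Dong-R4
Penelope	LINE	Penelope
Athena	LINE	Penelope
Coprina	LINE	Penelope
Chlamys	LINE	Penelope
Neptune	LINE	Penelope
Poseidon	LINE	Penelope
Proto1	LINE	
Proto2	LINE	Proto2
RandI	LINE	
Tad1	LINE	Tad1
LINE	LINE	
Non-LTR Retrotransposon	LINE	
SINE	SINE	
SINE1/7SL	SINE	7SL
SINE2/tRNA	SINE	tRNA
SINE3/5S	SINE	5S
SINE4	SINE	
DeuSINE	SINE	
V-SINE	SINE	
Alu	SINE	Alu
B1	SINE	Alu
MIR	SINE	MIR
ID	SINE	tRNA
B2	SINE	tRNA
B4	SINE	tRNA
7SL	SINE	7SL
5S	SINE	5S
SVA	Retroposon	SVA
Retroposon	Retroposon	
L1-dependent Retroposon	Retroposon	
Helitron	RC	Helitron
Helitron1	RC	Helitron
Helitron2	RC	Helitron
Helentron	RC	Helitron
SAT	Satellite	
MSAT	Satellite	
Satellite	Satellite	
CEN	Satellite	centr
Centromeric Satellite	Satellite	centr
rRNA	rRNA	
18S rRNA	rRNA	
28S rRNA	rRNA	
5.8S rRNA	rRNA	
tRNA	tRNA	
Mariner/Tc1	DNA	TcMar
Tc1	DNA	TcMar
Mariner	DNA	TcMar
Pogo	DNA	TcMar
Tigger	DNA	TcMar
Stowaway	DNA	TcMar
hAT	DNA	hAT
Charlie	DNA	hAT
Blackjack	DNA	hAT
Tip100	DNA	hAT
Ac	DNA	hAT
hobo	DNA	hAT
EnSpm/CACTA	DNA	CMC-EnSpm
EnSpm	DNA	CMC-EnSpm
CACTA	DNA	CMC-EnSpm
Chapaev	DNA	CMC-EnSpm
Mirage	DNA	CMC-EnSpm
Transib	DNA	CMC-Transib
MuDR	DNA	MULE-MuDR
MULE	DNA	MULE-MuDR
Mutator	DNA	MULE-MuDR
Harbinger	DNA	PIF-Harbinger
PIF	DNA	PIF-Harbinger
PIF-Harbinger	DNA	PIF-Harbinger
PiggyBac	DNA	PiggyBac
P	DNA	P
P-element	DNA	P
Merlin	DNA	Merlin
Crypton	DNA	Crypton
CryptonA	DNA	Crypton
CryptonF	DNA	Crypton
CryptonI	DNA	Crypton
CryptonS	DNA	Crypton
CryptonV	DNA	Crypton
Kolobok	DNA	Kolobok
Polinton	DNA	Maverick
Maverick	DNA	Maverick
Sola	DNA	Sola
Sola1	DNA	Sola
Sola2	DNA	Sola
Sola3	DNA	Sola
IS3EU	DNA	
ISL2EU	DNA	
Zator	DNA	
Academ	DNA	
Novosib	DNA	
Dada	DNA	
Ginger1	DNA	
Ginger2	DNA	
Zisupton	DNA	
DNA Transposon	DNA	
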