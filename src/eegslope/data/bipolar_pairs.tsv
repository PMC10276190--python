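# anode	cathode	virtual
Fp1	Fp2	Fp1-Fp2
AF7	AF3	AF7-AF3
AF3	AF4	AF3-AF4
AF4	AF8	AF4-AF8
F7	F5	F7-F5
F5	F3	F5-F3
F3	F1	F3-F1
F1	Fz	F1-Fz
Fz	F2	Fz-F2
F2	F4	F2-F4
F4	F6	F4-F6
F6	F8	F6-F8
FT9	FT7	FT9-FT7
FT7	FC5	FT7-FC5
FC5	FC3	FC5-FC3
FC3	FC1	FC3-FC1
FC1	FC2	FC1-FC2
FC2	FC4	FC2-FC4
FC4	FC6	FC4-FC6
FC6	FT8	FC6-FT8
FT8	FT10	FT8-FT10
T7	C5	T7-C5
C5	C3	C5-C3
C3	C1	C3-C1
C1	Cz	C1-Cz
Cz	C2	Cz-C2
C2	C4	C2-C4
C4	C6	C4-C6
C6	T8	C6-T8
TP9	TP7	TP9-TP7
TP7	CP5	TP7-CP5
CP5	CP3	CP5-CP3
CP3	CP1	CP3-CP1
CP1	CPz	CP1-CPz
CPz	CP2	CPz-CP2
CP2	CP4	CP2-CP4
CP4	CP6	CP4-CP6
CP6	TP8	CP6-TP8
TP8	TP10	TP8-TP10
P7	P5	P7-P5
P5	P3	P5-P3
P3	P1	P3-P1
P1	Pz	P1-Pz
Pz	P2	Pz-P2
P2	P4	P2-P4
P4	P6	P4-P6
P6	P8	P6-P8
PO9	PO7	PO9-PO7
PO7	PO3	PO7-PO3
PO3	POz	PO3-POz
POz	PO4	POz-PO4
PO4	PO8	PO4-PO8
PO8	PO10	PO8-PO10
O1	Oz	O1-Oz
Oz	O2	Oz-O2
Fp1	AF3	Fp1-AF3
Fp2	AF4	Fp2-AF4
Fp1	AF7	Fp1-AF7
Fp2	AF8	Fp2-AF8
AF7	F7	AF7-F7
AF3	F3	AF3-F3
AF4	F4	AF4-F4
AF8	F8	AF8-F8
AF3	F1	AF3-F1
AF4	F2	AF4-F2
F7	FT7	F7-FT7
F5	FC5	F5-FC5
F3	FC3	F3-FC3
F1	FC1	F1-FC1
F2	FC2	F2-FC2
F4	FC4	F4-FC4
F6	FC6	F6-FC6
F8	FT8	F8-FT8
FT7	T7	FT7-T7
FC5	C5	FC5-C5
FC3	C3	FC3-C3
FC1	C1	FC1-C1
FC2	C2	FC2-C2
FC4	C4	FC4-C4
FC6	C6	FC6-C6
FT8	T8	FT8-T8
T7	TP7	T7-TP7
C5	CP5	C5-CP5
C3	CP3	C3-CP3
C1	CP1	C1-CP1
Cz	CPz	Cz-CPz
C2	CP2	C2-CP2
C4	CP4	C4-CP4
C6	CP6	C6-CP6
T8	TP8	T8-TP8
TP7	P7	TP7-P7
CP5	P5	CP5-P5
CP3	P3	CP3-P3
CP1	P1	CP1-P1
CPz	Pz	CPz-Pz
CP2	P2	CP2-P2
CP4	P4	CP4-P4
CP6	P6	CP6-P6
TP8	P8	TP8-P8
P7	PO7	P7-PO7
P3	PO3	P3-PO3
Pz	POz	Pz-POz
P4	PO4	P4-PO4
P8	PO8	P8-PO8
P5	PO3	P5-PO3
PO7	O1	PO7-O1
PO3	O1	PO3-O1
POz	Oz	POz-Oz
PO4	O2	PO4-O2
PO8	O2	PO8-O2
PO9	O1	PO9-O1
PO10	O2	PO10-O2
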