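drug	Hs 919.T	RD-ES	SK-ES-1	A673
Topotecan HCl	< 50	97	96	97
Irinotecan Hydrochloride	< 50	99	98	83
Melphalan	< 50	95	91	< 50
Paclitaxel/Taxol	< 50	97	96	96
Auranofin	< 50	100	99	98
Estradiol	< 50	< 50	< 50	65
Methyltestosterone	< 50	73	< 50	< 50
Vorinostat	< 50	61	< 50	< 50
Nitrofural/Nitrofurazone	< 50	52	72	52
Clemastine	< 50	< 50	< 50	60
Ebselen	< 50	95	96	93
Methotrexate/Amethopterin (R,S)	< 50	82	< 50	89
L-Glutamic acid, N-[4-[[(2,4-diamino-6-pteridinyl)methyl]methylamino]benzoyl]	< 50	77	57	85
Cytosine beta-D-arabinofuranoside/Cytarabine	< 50	93	98	84
Rapamycin	< 50	62	51	67
Mycophenolic Acid	< 50	52	< 50	< 50
Cycloheximide	< 50	74	81	77
(+)-Tubocurarine chloride	< 50	51	< 50	< 50
Atractyloside potassium salt	< 50	98	99	99
Ticlopidine	< 50	< 50	< 50	66
Antimycin A	< 50	69	< 50	< 50
Pyrvinium pamoate	< 50	98	96	84
Isoniazid	< 50	< 50	< 50	56
Trifluridine	< 50	71	< 50	< 50
Floxuridine	< 50	92	56	68
Azathioprine	< 50	< 50	52	< 50
Mercaptopurine	< 50	< 50	57	< 50
Thioguanosine	< 50	< 50	64	73
Clofarabine	< 50	99	98	93
Cladribine	< 50	99	89	87
Azaguanine-8	< 50	< 50	< 50	83
Cyclocytidine	< 50	83	98	86
Albendazole	< 50	93	93	89
Fenbendazole	< 50	86	78	75
Mebendazole	< 50	95	96	94
Flubendazole	< 50	86	86	77
Oxibendazole	< 50	80	84	64
Oseltamivir	< 50	95	98	95
Disulfiram	< 50	96	95	99
Raltitrexed	< 50	80	51	59
Novobiocin sodium	< 50	51	< 50	60
Amorolfine	< 50	< 50	< 50	56
Camptothecine (S,+)	< 50	97	96	99
AM 404	< 50	< 50	< 50	65
Etoposide	< 50	84	84	< 50
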