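genotype	Abaya	Agawayu	Bako	Bedeno	Daro Lebu	Delo Mena	Girja	Sewena	Yabello
Amibara 2	4.05	2.45	3.05	3.55	4.45	2.90	1.70	2.60	4.15
Ardi	2.65	2.40	2.30	5.40	6.55	1.95	1.85	2.55	3.85
Balcha	3.55	2.20	1.85	3.95	4.80	2.35	1.60	2.75	4.75
Deka	2.90	2.05	2.45	3.50	4.05	2.40	1.50	2.60	3.65
ETBW 9554	2.75	2.35	2.75	3.65	4.35	2.35	1.55	2.60	3.80
ETBW 9578	3.60	3.15	2.35	3.75	4.75	2.60	3.00	2.45	4.70
Fentale 2	3.50	3.10	2.80	4.00	4.55	2.55	1.80	2.90	3.95
Fentale 1	4.20	3.35	2.80	4.80	5.20	2.90	2.60	2.80	3.95
Ga'ambo 2	2.25	2.65	3.15	3.50	4.45	2.55	1.65	2.50	3.60
Kekeba	3.15	2.65	2.70	4.00	5.40	1.95	2.70	2.45	3.45
Ogolcho	2.90	2.55	3.80	3.75	3.95	2.40	1.40	2.65	3.65
Pavon 76	2.75	2.10	3.00	3.70	5.20	2.65	2.05	2.65	3.90
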