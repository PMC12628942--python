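rank	name	rrn
genus	Bacillus	9.4
genus	Vibrio	9.0
genus	Clostridium	8.5
genus	Streptomyces	6.1
genus	Pseudomonas	5.2
genus	Paenibacillus	7.3
genus	Arthrobacter	5.0
genus	Microvirga	3.5
genus	Geodermatophilus	2.8
genus	Pseudonocardia	2.4
genus	Skermanella	2.2
genus	Sphingomonas	2.0
genus	Balneimonas	2.0
genus	Mycobacterium	1.8
genus	Rubrobacter	1.5
genus	Conexibacter	1.4
genus	Solirubrobacter	1.2
genus	Rhodoplanes	1.2
genus	Bradyrhizobium	1.0
genus	Nitrospira	1.0
family	Bacillaceae	8.9
family	Micrococcaceae	4.2
family	Sphingomonadaceae	2.1
family	Rubrobacteraceae	1.5
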