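genus	guild
Alternaria	Pathotroph-Saprotroph-Symbiotroph
Fusarium	Pathotroph-Saprotroph
Ophiobolus	Pathotroph
Botryosphaeria	Pathotroph
Curvularia	Pathotroph-Saprotroph
Aspergillus	Saprotroph
Penicillium	Saprotroph
Mortierella	Saprotroph
Chaetomium	Saprotroph
Preussia	Saprotroph
Trichoderma	Saprotroph-Symbiotroph
Glomus	Symbiotroph
Rhizophagus	Symbiotroph
Darksidea	Symbiotroph
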