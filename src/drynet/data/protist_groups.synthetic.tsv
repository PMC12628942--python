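genus	group
Cercomonas	consumer
Euglypha	consumer
Acanthamoeba	consumer
Vannella	consumer
Heteromita	consumer
Bodo	consumer
Spumella	consumer
Chlamydomonas	phototroph
Chlorella	phototroph
Navicula	phototroph
Klebsormidium	phototroph
Phytophthora	pathotroph
Pythium	pathotroph
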