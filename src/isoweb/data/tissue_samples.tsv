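category	count
primary_producers	1042
invertebrates	1476
fish	2821
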