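# Reconstructed microbe-substrate-metabolite-target chain table (25 nodes,
# 23 edges after assembly).  The wiring of the Unknown placeholders to named
# metabolites is a documented reconstruction; node/edge counts and the
# five-metabolite IL6 hub are the tested contract.
microbe	substrate	metabolite	target
Escherichia coli	Tryptophan	Indole	AKT1
Lactobacillus paracasei JS1	Isoflavone	Equol	IL6
Enterococcus durans M4-5	Unknown 5	3-Indolepropionic acid	IL6
Unknown 1	Unknown 6	Trimethylamine oxide	IL6
Unknown 2	Unknown 7	Butyrate	IL6
Eubacterium limosum	Unknown 8	Acetate	IL6
Escherichia coli	Unknown 8	Acetate	IL6
Unknown 3	Unknown 8	Acetate	IL6
Unknown 4	Unknown 9	Unknown 10	ALB
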