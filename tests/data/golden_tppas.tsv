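group	cell_type	tppas	n_genes
MS	astrocyte	17.96701645	11
MS	microglia_macrophage	2.675974705	12
MS	oligodendrocyte	10.80322573	12
control	astrocyte	-3.65954908	11
control	microglia_macrophage	14.36894443	11
control	oligodendrocyte	5.700442409	11
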