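# demo pipeline: simulate all inputs, fit curves, run the phenotype models,
# the haplotype scan, the family dissection, and the selection scan
seed: 0
stages: [simulate, curves, pheno, haploscan, dissect, scan]
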