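# Fixed-seed demo for `retpoise run --config examples/demo.yaml`
seed: 5
outdir: demo_run
sim:
  chrom_length: 400000
  n_genes: 20
  n_tres: 12
  ligand_tail_fraction: 0.13
refine:
  fdr_target: 0.10
  n_decoys: 20
  max_train: 800
motifs:
  background_n_min: 50
score:
  ligand_genes: [GDNF, NRTN, ARTN, PSPN]
  er_positive_only: true
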