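# Demo pipeline configuration: simulate a small study end to end.
outdir: demo_out
seed: 7
strong_z: 2.0
weak_z: 1.0
alpha: 0.1
fpkm_cut: 1.0
tpm_cut: 1.0
bin_lo: 1.3
bin_hi: 1.7
min_wells: 8
transchromosomic: false
control_label: GFP
simulate:
  n_cdnas: 24
  replicates_per_cdna: 8
  n_inhibitors: 3
  inhibitor_effect: 0.6
  n_activators: 2
  activator_effect: 1.6
  n_genes: 200
  n_trisomic_genes: 40
  dispersion: 0.05
  library_size: 1.0e6
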