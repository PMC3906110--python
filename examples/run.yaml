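# Full synthetic study: two groups of 8 samples, one cistron with a planted
# 9.2-fold (log2FC 3.2) elevation, decoys for the mining stage.
seed: 1
out_dir: cystmir_run
simulation:
  n_samples_per_group: 8
  n_mirna: 24
  n_clusters: 9
  mean_library_size: 20000
  dispersion: 0.2
  planted_log2fc: {miR-s07: 3.2, miR-s08: 3.2, miR-s09: 3.2}
  baseline_cpm: {miR-s07: 300.0, miR-s08: 500.0, miR-s09: 200.0}
  decoy_rpm: {decoy-hi: 250.0, decoy-lo: 50.0}
de:
  unit_system: cistron
  min_cpm: 1.0
  dispersion: tagwise
variants:
  alpha: 0.1
  min_mirna_reads: 20
mining:
  threshold_rpm: 200.0
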