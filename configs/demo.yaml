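# End-to-end demo: two 10-Mb chromosomes, 2,000 markers, 15 descendant
# lines bred under selection at two loci, and a 240-line DH population
# phenotyped for one additive trait in 3 environments x 2 replicates.
seed: 1
simulate:
  n_chrom: 2
  markers_per_chrom: 1000
  chrom_len_bp: 10000000
  chrom_len_cM: 100.0
  delta: 0.6
  n_descendants: 15
  n_candidates_per_cycle: 60
  n_cycles: 3
  selected_loci:
    - {chrom: chr1, pos_bp: 5000000, weight: 3.0, favored: 1}
    - {chrom: chr2, pos_bp: 2500000, weight: 2.0, favored: 2}
  dh_n: 240
  qtls:
    - {trait: yield, chrom: chr1, pos_cM: 30.0, a: 1.0}
    - {trait: yield, chrom: chr2, pos_cM: 70.0, a: -0.7}
  h2: {yield: 0.6}
  n_env: 3
  n_rep: 2
ibd:
  min_lod: 3.0
  trim_lod: 2.5
  error_rate: 0.0001
  min_markers: 5
  tau: 0.9
  icr_window_bp: 100000
sweep:
  window_bp: 10000
  agg_bp: 100000
  top_fraction: 0.10
qtl:
  step_cM: 0.5
  p_in: 0.001
  lod_threshold: 2.5
  # narrower cofactor window + deeper valley requirement suppress satellite
  # peaks on the strong-signal demo trait
  cofactor_excl_cM: 10.0
  valley_drop_lod: 2.5
coloc:
  near_dist: 1000000
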