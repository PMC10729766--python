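# Full pipeline configuration: four breeds with the unbalanced design
# (one breed at n = 14), desk-scale SNP count, synthetic 18-autosome map.
breeds: [D, H, L, W]
breed_names: [Duroc, Hampshire, Landrace, LargeWhite]
p: 2000
fst: 0.15
maf_min: 0.045
admix_mean: 0.09
n_per_breed: [200, 14, 200, 200]
n_chrom: 18
cm_per_mb: 1.0
# map_path: my_map.tsv        # 3-column TSV (chrom, pos_bp, cum_cM) overrides the synthetic map
m: null                       # PLS components; null = q - 1
alpha0: estimate              # or a fixed positive number, e.g. 73.58
alpha0_sims: 1000
prior: flat                   # or a path to a (label, probability) CSV
pi_unknown: null              # optional override of the unknown-class prior
n_per_combo: 100              # simulated crossbreds per combination
filter_maf_min: 0.01
filter_callrate_min: 0.9
seed: 1
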