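# Demo-scale pipeline run: completes on one CPU in a few minutes.
out_dir: run_demo
seed: 0
n_jobs: 1
synthetic:
  n_sets: 20
  n_vertices: 50
  n_participants: 12
  embedding_dim: 24
  probe_rank: 12
  embedding_noise_sd: 0.05
time_stride: 5
n_perm_cluster: 500
n_perm_spearman: 2000
effect_size: 1.0
effect_n_vertices: 8
nmf_k_max: 5
nmf_restarts: 5
gc_max_order: 5
gc_surrogates: 200
probe_n_restarts: 10
probe_max_iter: 1500
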