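# Example configuration for `nanolem equivalence-report --config ...`
# All keys optional; defaults shown.
size_classes: [70, 250, 500]   # bounding radii, nm (333 NPs at r_bound/10 each)
n_np: 333
r_cell_um: 15.0
r_nucleus_um: 7.0
cell_line:
  alpha: 0.2        # 1/Gy
  beta: 0.05        # 1/Gy^2
  dose_gy: 2.0      # macroscopic prescription D
d_start_um: 7.0     # scan floor = nucleus radius (source outside nucleus)
d_stop_um: 40.0     # beyond the cell: cross-fire from neighboring cells
d_step_um: 0.05
seed: 12345
noise_rel: 0.02     # worst-bin relative MC uncertainty of the synthetic RDDs
dose_scale: 1.0     # linear conversion of the RDD scale to Gy
d_from_nucleus_surface: false   # alternate position convention
normalize: false    # divide scan curves by the cluster's cytoplasm I1
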