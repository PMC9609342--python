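# Default end-to-end study configuration (mirrors PipelineConfig()).
#
# This is a DESK-SCALED study sized for a single CPU: the wavenumber axis is
# 6x coarser than the 2.83 cm^-1 hardware grid (196 instead of 1175
# channels), the CNN trains for 100 epochs instead of 200, and RMSECV uses
# 3 folds.  Channel noise and per-batch interference bands are turned up so
# that characteristic-band selection has junk to remove.  For a full-scale
# run set axis_resolution: 2.83, window: 11, max_epochs: 200, eval_folds: 5
# and plan for hours of CPU time.

seed: 0

simulate:
  n_batches: 7
  replicates: 3
  drop_last: true          # 7 batches x 48 points = 336; trimmed to 335
  outlier_count: 5
  axis_resolution: 16.98   # cm^-1 (6 x 2.83)
  noise_sd: 0.35
  baseline_scale: 0.1
  interferent_scale: 1.2
  interferent_peaks: 20

preprocess:
  window: 5                # Savitzky-Golay window (channels); 11 at 2.83 cm^-1
  polyorder: 3

screen:
  rule: mean3sd
  k: 3.0
  n_scores: auto           # 95% variance, capped at 10 PCA scores

split_ratio: "4:1"

select:
  cars_runs: 50
  cars_mc_rate: 0.8
  folds: 5

cnn:
  max_epochs: 100
  patience: 40
  batch_size: 50
  learning_rate: 1.0e-4

engines: [spa-svr, cars-plsr, cnn, cars-cnn]
attributes: [danshensu, ferulic_acid, rosmarinic_acid, salvianolic_acid_b, soluble_solid]
eval_folds: 3
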