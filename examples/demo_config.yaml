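# Demo pipeline run: 30 infants, recordings at 5 PMA weeks,
# 30-minute analysis windows. Run with:
#   neomat run examples/demo_config.yaml
# or python examples/run_full_pipeline.py
outdir: scratch/demo_run
seed: 17
n_infants: 30
recording_pma_weeks: [32, 33, 34, 35, 36]
recording_duration_s: 1900
window_s: 1800
min_quality: 0.8
min_beats: 1000
subset_size: 8
ga_population: 10
ga_generations: 5
n_trees: 100
trajectory_window: [32, 36]
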