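# One-shot pipeline run over a simulated 9+9 cohort:
#   python -c "from scpoim.pipeline import RunConfig, run_all; run_all(RunConfig.from_yaml('analysis/demo_config.yaml'))"
out_dir: results/run
seed: 7
sample_rate: 100.0
n_scales: 3          # 3 scales per type -> 6 states -> 160 features
T: 10
final_k: 2
curve_k_max: 10
leakage: fold        # each LOO fold re-ranks features on its own training dialogs
simulate:
  n_dialogs: 9
  dialog_length: 150
  effect: 0.3
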