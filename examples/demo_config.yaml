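# Full schema for `replitime run --config <file>`.
# Omitted keys take these defaults.
seed: 1
bin_width: 300
chromosomes:
  - [chrI, 2200000]
  - [chrII, 1600000]
  - [chrIII, 1200000]
conditions:
  control: {fork_speed_kb_min: 1.0}
  mutant: {fork_speed_kb_min: 0.8}
reference_condition: control
timepoints: [60, 70, 75, 80, 85, 90, 160]
fit_timepoints: [70, 75, 80, 85, 90]
ip_depth: 100
input_depth: 100
at_bias: true
hu_arrest_kb: 20.0          # replication extent around origins under HU
dotblot_noise_sd: 0.0       # multiplicative log-normal noise on dot-blot signal
compare_g: 0.5              # global extent for the condition contrast
overlay_g: 0.3              # global extent for peak-normalised overlays
thresholds:
  min_input_count: 5        # mask bins with fewer raw input reads
  min_at: 0.05              # mask bins with lower A/T ratio
  half_window_bins: 8       # moving-average half window
  min_prominence_frac: 0.25 # origin peak prominence, fraction of dynamic range
  min_separation_kb: 9.0    # minimum origin separation
  shoulder_min_kb: 15.0     # replication-track shoulder requirement
  k_sd: 2.0                 # deviant-late threshold in origin-class SDs
gel:
  fragment_mean_kb: {control: 4.0, mutant: 2.0}
  n_fragments: 200000
  band_sd_px: 2.0
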