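# Default stratum profiles for the synthetic interval-elicitation generator.
# Version 1.  Centers are inspired by the per-level confidence bands reported
# for the two rater strata of the severity-perception study ("inspired-by"
# values for emulation, never asserted as estimates).
version: 1
profiles:
  doctor:
    level_centers:
      Absent: 9.0
      Mild: 26.0
      Moderate: 47.0
      Severe: 67.5
      Extreme: 88.0
    center_sd: 8.0
    half_width_mean: 10.0
    half_width_sd: 4.0
    rp_jitter_sd: 5.0
  patient:
    level_centers:
      Absent: 13.8
      Mild: 26.6
      Moderate: 41.3
      Severe: 58.0
      Extreme: 70.8
    center_sd: 8.0
    half_width_mean: 10.0
    half_width_sd: 4.0
    rp_jitter_sd: 5.0
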