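# Generating-truth and noise presets for the synthetic modified-basecall simulator.
#
# Truth probabilities are per (strand, region): '+' is the coding C-rich
# strand, '-' the template G-rich strand. The dnmt3a region x strand means
# and the msssi level are *inputs* to the generator (taken from the reported
# study values), so downstream recovery of these numbers validates the
# pipeline, not the study.
#
# Noise model: each call is drawn from a Dirichlet centred on the truth state
# (concentration high_conf_concentration on the truth state,
# off_state_concentration elsewhere), except that with probability
# p_low_conf_inside_pqs / p_low_conf_outside the call comes from a
# near-uniform Dirichlet (symmetric low_conf_concentration) instead.
# false_mod_rate is the probability that an unmethylated truth emits a
# confident *modified* call (5mC with probability false_5mC_fraction, else
# 5hmC).
#
# Calibration: the control false_mod_rate of 0.052 was chosen so that the
# 0.65-thresholded global 5mC level of the control preset lands near 0.04
# (retained-call algebra: ~0.747 x false_mod_rate + 0.001 at the default
# region mix); the methylated presets use a smaller 0.01 so that recovered
# region x strand means stay within a point of their generating truth.
control:
  truth:
    "+": {PQS: 0.0, non-PQS: 0.0}
    "-": {PQS: 0.0, non-PQS: 0.0}
  noise:
    high_conf_concentration: 30.0
    off_state_concentration: 0.5
    low_conf_concentration: 5.0
    p_low_conf_inside_pqs: 0.30
    p_low_conf_outside: 0.02
    false_mod_rate: 0.052
    false_5mC_fraction: 0.75
    site_jitter_sd: 0.0
dnmt3a:
  truth:
    "+": {PQS: 0.58, non-PQS: 0.49}
    "-": {PQS: 0.33, non-PQS: 0.47}
  noise:
    high_conf_concentration: 30.0
    off_state_concentration: 0.5
    low_conf_concentration: 5.0
    p_low_conf_inside_pqs: 0.30
    p_low_conf_outside: 0.02
    false_mod_rate: 0.01
    false_5mC_fraction: 0.75
    site_jitter_sd: 0.12
msssi:
  truth:
    "+": {PQS: 0.62, non-PQS: 0.62}
    "-": {PQS: 0.62, non-PQS: 0.62}
  noise:
    high_conf_concentration: 30.0
    off_state_concentration: 0.5
    low_conf_concentration: 5.0
    p_low_conf_inside_pqs: 0.30
    p_low_conf_outside: 0.02
    false_mod_rate: 0.01
    false_5mC_fraction: 0.75
    site_jitter_sd: 0.12
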