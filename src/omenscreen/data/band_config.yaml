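# Default sliding-window detector configuration per EEG band.
# Window lengths (4 s / 3 s) match the typical 3-6 s temporal scale of
# hazardous-omen perception at the 250 Hz feature sampling rate; the
# exceedance rule is mu + 3*sigma of the baseline T statistic sustained
# for at least 0.5 s; alpha is the per-band significance level of the
# scan-maximum test.
bands:
  alpha:
    window_s: 4.0
    window_samples: 1000
    sampling_rate_hz: 250
    k_sigma: 3.0
    min_duration_s: 0.5
    alpha: 0.042
  beta:
    window_s: 4.0
    window_samples: 1000
    sampling_rate_hz: 250
    k_sigma: 3.0
    min_duration_s: 0.5
    alpha: 0.087
  theta:
    window_s: 3.0
    window_samples: 750
    sampling_rate_hz: 250
    k_sigma: 3.0
    min_duration_s: 0.5
    alpha: 0.035
  delta:
    window_s: 3.0
    window_samples: 750
    sampling_rate_hz: 250
    k_sigma: 3.0
    min_duration_s: 0.5
    alpha: 0.061
  gamma:
    window_s: 3.0
    window_samples: 750
    sampling_rate_hz: 250
    k_sigma: 3.0
    min_duration_s: 0.5
    alpha: 0.029
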