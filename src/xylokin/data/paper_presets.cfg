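stand_id: S2012
planting_year: 2012
n_trees: 5
A_mean: 358.5
A_sd: 53.775
beta: 1.68
k: 0.0064
pulse_split: 0.55
pulse2_offset: 90.0
enlarge_days: 18.0
thicken_days: 40.0
cambial_baseline: 2.5
cambial_gain: 6.0
noise_model: poisson
noise_sd: 1.0
sampling_interval_days: 9
season_start_doy: 51
season_end_doy: 339

stand_id: S2006
planting_year: 2006
n_trees: 5
A_mean: 116.4
A_sd: 17.46
beta: 1.46
k: 0.0073
pulse_split: 0.55
pulse2_offset: 90.0
enlarge_days: 18.0
thicken_days: 40.0
cambial_baseline: 2.5
cambial_gain: 6.0
noise_model: poisson
noise_sd: 1.0
sampling_interval_days: 9
season_start_doy: 51
season_end_doy: 339

stand_id: S2000
planting_year: 2000
n_trees: 5
A_mean: 243.4
A_sd: 36.51
beta: 1.67
k: 0.0073
pulse_split: 0.55
pulse2_offset: 90.0
enlarge_days: 18.0
thicken_days: 40.0
cambial_baseline: 2.5
cambial_gain: 6.0
noise_model: poisson
noise_sd: 1.0
sampling_interval_days: 9
season_start_doy: 51
season_end_doy: 339

stand_id: S1993
planting_year: 1993
n_trees: 5
A_mean: 123.4
A_sd: 18.51
beta: 1.49
k: 0.0075
pulse_split: 0.55
pulse2_offset: 90.0
enlarge_days: 18.0
thicken_days: 40.0
cambial_baseline: 2.5
cambial_gain: 6.0
noise_model: poisson
noise_sd: 1.0
sampling_interval_days: 9
season_start_doy: 51
season_end_doy: 339

stand_id: S1969
planting_year: 1969
n_trees: 5
A_mean: 94.7
A_sd: 14.205
beta: 1.38
k: 0.0077
pulse_split: 0.55
pulse2_offset: 90.0
enlarge_days: 18.0
thicken_days: 40.0
cambial_baseline: 2.5
cambial_gain: 6.0
noise_model: poisson
noise_sd: 1.0
sampling_interval_days: 9
season_start_doy: 51
season_end_doy: 339
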