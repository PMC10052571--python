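# Reduced demonstration configuration: 3 x 5 stand, 5-day window, coarse
# tessellation. The full study setup is 10 x 15 plants and 60 days
# (layout: n_rows 10, n_cols 15, focal 3 x 3; n_days: 60).
layout:
  n_rows: 3
  n_cols: 5
  focal_rows: 1
  focal_cols: 3
seed: 1
n_segments: 4
n_width_strips: 1
n_days: 5
doy_start: 233
peak_par: 1800.0
diffuse_fraction: 0.25
n_sky_sectors: 46
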