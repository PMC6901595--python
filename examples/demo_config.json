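{
  "acquisition": {
    "rep_rate_hz": 80000000.0,
    "n_time_bins": 256,
    "image_shape": [96, 96],
    "lambda_min_nm": 410.0,
    "lambda_max_nm": 696.0,
    "n_channels": 32,
    "channel_width_nm": 8.9,
    "harmonic": 1,
    "irf_fwhm_ps": 0.0
  },
  "scene": {
    "kind": "melanocytes",
    "n_cells": 4,
    "granules_per_cell": 45,
    "granule_photons": 4000.0,
    "soma_photons": 200.0,
    "background_species": ["nadh"],
    "snr_scale_spectral": 0.5
  },
  "analysis": {
    "harmonic": 1,
    "intensity_threshold": 20.0,
    "efilter_passes": 1,
    "efilter_kernel": 3,
    "n_cursors": 7,
    "cursor_radius": 0.05,
    "alpha": 0.05,
    "n_regions": 15
  },
  "modality": "both",
  "seed": 7
}
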