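# Chlamydomonas reinhardtii isolated wild-type centrioles.
# Wall-protein channels: POC16 sits on the microtubule wall (zero radial
# offset), POB15 is shifted 12 nm toward the lumen; both cover ~40% of the
# centriole length in the central core.
name: cr-wildtype
calibration:
  gel_size_mm: 50.0
  coverslip_mm: 12.0
  pixel_nm: 35.0
  z_step_nm: 120.0
centriole:
  wall_radius_nm: 110.0
  n_triplets: 9
  wall_sigma_nm: 8.0
  tubulin_length_nm: {mean: 495.0, sd: 33.0}
  ellipse_ratio: 1.0
  break_prevalence: 0.0
  break_arc_deg: 0.0
channels:
  POC16:
    offset_nm: 0.0
    offset_sd_nm: 4.0      # half the observed per-measurement scatter (8 nm)
    coverage: {mean: 0.41, sd: 0.11}
    position: centered
  POB15:
    offset_nm: 12.0
    offset_sd_nm: 3.5
    coverage: {mean: 0.40, sd: 0.06}
    position: centered
imaging:
  psf_fwhm_nm: 140.0
  photon_scale: 500.0
  read_noise_sd: 3.0
  background: 10.0
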