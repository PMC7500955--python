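# Human U2OS centrioles, control siRNA condition.
# Inner-scaffold channels (POC1B, FAM161A, POC5, Centrin) sit progressively
# deeper toward the lumen; WDR90 sits essentially on the microtubule wall.
# The inner scaffold covers ~57% of the tubulin length, centered on the
# central core.
name: hs-control
calibration:
  gel_size_mm: 50.0
  coverslip_mm: 12.0
  pixel_nm: 35.0
  z_step_nm: 120.0
centriole:
  wall_radius_nm: 110.0
  n_triplets: 9
  wall_sigma_nm: 8.0
  tubulin_length_nm: {mean: 434.0, sd: 58.0}
  ellipse_ratio: 1.0
  break_prevalence: 0.0
  break_arc_deg: 0.0
channels:
  WDR90:
    offset_nm: 2.0
    offset_sd_nm: 6.0
    coverage: {mean: 0.46, sd: 0.17}
    position: centered
  POC1B:
    offset_nm: 15.0
    offset_sd_nm: 4.0
    coverage: {mean: 0.57, sd: 0.13}
    position: centered
  FAM161A:
    offset_nm: 22.0
    offset_sd_nm: 2.5
    coverage: {mean: 0.57, sd: 0.13}
    position: centered
  POC5:
    offset_nm: 27.0
    offset_sd_nm: 3.0
    coverage: {mean: 0.57, sd: 0.13}
    position: centered
  Centrin:
    offset_nm: 28.0
    offset_sd_nm: 4.5
    coverage: {mean: 0.57, sd: 0.13}
    position: centered
imaging:
  psf_fwhm_nm: 140.0
  photon_scale: 500.0
  read_noise_sd: 3.0
  background: 10.0
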