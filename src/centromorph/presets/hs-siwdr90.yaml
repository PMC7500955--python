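# Human U2OS centrioles depleted of WDR90 (siRNA).
# Centrioles elongate slightly, the inner-scaffold belt shrinks to ~24% of
# the tubulin length and sits at the proximal extremity of the core region,
# 10% of centrioles show a broken microtubule wall, and top views lose their
# round shape (ellipse ratio drawn below 1).
name: hs-siwdr90
calibration:
  gel_size_mm: 50.0
  coverslip_mm: 12.0
  pixel_nm: 35.0
  z_step_nm: 120.0
centriole:
  wall_radius_nm: 110.0
  n_triplets: 9
  wall_sigma_nm: 8.0
  tubulin_length_nm: {mean: 500.0, sd: 65.0}
  ellipse_ratio: {min: 0.70, max: 0.95}
  break_prevalence: 0.10
  break_arc_deg: 60.0
channels:
  POC1B:
    offset_nm: 15.0
    offset_sd_nm: 4.0
    coverage: {mean: 0.24, sd: 0.14}
    position: proximal
  POC5:
    offset_nm: 27.0
    offset_sd_nm: 3.0
    coverage: {mean: 0.24, sd: 0.14}
    position: proximal
imaging:
  psf_fwhm_nm: 140.0
  photon_scale: 500.0
  read_noise_sd: 3.0
  background: 10.0
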