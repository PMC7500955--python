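# Decorated-microtubule line profile: tubulin/WDR90-N oligomer bumps
# repeating every 8.5 nm along the microtubule lattice.
name: wdr90-decoration
profile:
  period_nm: 8.5
  n_repeats: 20
  bump_fwhm_nm: 4.0
  noise_sd: 0.05
  sample_step_nm: 0.25
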