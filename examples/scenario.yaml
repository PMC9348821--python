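# Two genotypes across five light regimes: long and short photoperiods,
# short (T17) and long (T28) external cycles, and a sudden early dusk.
# The wild type holds starch exhaustion near 24 h after dawn with linear
# night mobilization; the clock mutant mobilizes fast-early (curvature
# 1.3), exhausts early, and has damped transcript oscillations.
# Transcripts are measured in the T24 regimes only.
seed: 1
sample_every_h: 2

regimes:
  - {cycle_length_h: 24, photoperiod_h: 12, irradiance: 160}
  - {cycle_length_h: 24, photoperiod_h: 6, irradiance: 160}
  - {cycle_length_h: 24, photoperiod_h: 12, irradiance: 160,
     perturbation: "early_dusk@8"}
  - {cycle_length_h: 17, photoperiod_h: 8.5, irradiance: 160,
     sample_every_h: 1.7, simulate_transcripts: false}
  - {cycle_length_h: 28, photoperiod_h: 14, irradiance: 160,
     simulate_transcripts: false}

genotypes:
  - name: wildtype
    starch:
      accum_rate: 1.0        # µmol gFW⁻¹ h⁻¹
      exhaustion_zt: 24.0    # starch runs out at the anticipated dawn
      curvature: 1.0
      noise_frac: 0.05
      n_reps: 4
    transcripts:
      - {gene: DAWN1, baseline: 10, amplitude: 3, peak_zt: 2,
         peak_width: 6, damping: 1.0, noise_sd: 0.3, anchor: dawn}
      - {gene: DUSK1, baseline: 9, amplitude: 2.5, peak_zt: 1,
         peak_width: 5, damping: 1.0, noise_sd: 0.3, anchor: dusk}

  - name: clock_mutant
    starch:
      accum_rate: 0.8
      exhaustion_zt: 22.0    # premature exhaustion
      curvature: 1.3         # fast-early mobilization
      noise_frac: 0.05
      n_reps: 4
    transcripts:
      - {gene: DAWN1, baseline: 10, amplitude: 3, peak_zt: 2,
         peak_width: 6, damping: 0.4, noise_sd: 0.3, anchor: dawn}
      - {gene: DUSK1, baseline: 9, amplitude: 2.5, peak_zt: 1,
         peak_width: 5, damping: 0.4, noise_sd: 0.3, anchor: dusk}
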