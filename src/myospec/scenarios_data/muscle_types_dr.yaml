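# Diffuse-reflectance variant of the muscle-types scenario: classes
# differ in heme chromophore load and scattering, with cardiac muscle
# carrying more deoxy-heme (deeper 500-600 nm bands and the ~760 nm
# feature).  Magnitudes are synthetic modeling choices.
seed: 0
n_per_class: 30
af_attenuation: true
instrument:
  grid: {n_points: 3648, lo_nm: 345.0, hi_nm: 1041.0}
  gain_jitter_sd: 0.05
  ambient_level: 50.0
  read_noise_sd: 20.0
  signal_scale: 1000.0
  white_center_nm: 800.0
  white_width_nm: 350.0
  white_amplitude: 4000.0
fluorophore_bands:
  collagen: {center_nm: 475.0, width_nm: 20.0, amplitude: 1.0}
  flavin: {center_nm: 550.0, width_nm: 20.0, amplitude: 1.0}
  porphyrin: {center_nm: 650.0, width_nm: 15.0, amplitude: 1.0}
chromophore_bands:
  oxy_heme:
    bands:
      - {center_nm: 542.0, width_nm: 12.0, strength: 0.8}
      - {center_nm: 576.0, width_nm: 12.0, strength: 1.0}
  deoxy_heme:
    bands:
      - {center_nm: 556.0, width_nm: 15.0, strength: 1.0}
      - {center_nm: 760.0, width_nm: 20.0, strength: 0.35}
classes:
  - name: Quad
    fluorophores:
      collagen: {mean: 1.0, cv: 0.2}
      flavin: {mean: 0.6, cv: 0.2}
      porphyrin: {mean: 0.2, cv: 0.2}
    chromophores:
      oxy_heme: {mean: 0.35, cv: 0.15}
      deoxy_heme: {mean: 0.2, cv: 0.15}
    scattering_amplitude: 1.0
    scattering_exponent: 1.0
  - name: Gastr
    fluorophores:
      collagen: {mean: 0.9, cv: 0.2}
      flavin: {mean: 0.7, cv: 0.2}
      porphyrin: {mean: 0.25, cv: 0.2}
    chromophores:
      oxy_heme: {mean: 0.4, cv: 0.15}
      deoxy_heme: {mean: 0.22, cv: 0.15}
    scattering_amplitude: 1.05
    scattering_exponent: 1.0
  - name: TA
    fluorophores:
      collagen: {mean: 1.1, cv: 0.2}
      flavin: {mean: 0.5, cv: 0.2}
      porphyrin: {mean: 0.15, cv: 0.2}
    chromophores:
      oxy_heme: {mean: 0.3, cv: 0.15}
      deoxy_heme: {mean: 0.18, cv: 0.15}
    scattering_amplitude: 0.95
    scattering_exponent: 1.1
  - name: Heart
    fluorophores:
      collagen: {mean: 0.6, cv: 0.2}
      flavin: {mean: 1.0, cv: 0.2}
      porphyrin: {mean: 0.6, cv: 0.2}
    chromophores:
      oxy_heme: {mean: 0.5, cv: 0.15}
      deoxy_heme: {mean: 0.5, cv: 0.15}
    scattering_amplitude: 1.1
    scattering_exponent: 0.9
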