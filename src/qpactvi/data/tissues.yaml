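# Literature-informed per-tissue property tables for the synthetic breast
# phantoms. Scalar entries are fixed values; two-element lists are uniform
# sampling ranges drawn once per phantom per tissue.
#
# optical:  mus (mm^-1, one value per wavelength 757/800/850 nm),
#           g (anisotropy), n (refractive index)
# acoustic: c (m/s), rho (kg/m^3), alpha0 (dB MHz^-y cm^-1), y (power-law exp.)
# functional: volume fractions in [0, 1]; so2 as fraction of oxygenated Hb.
version: 1
whole_blood_thb_mM: 2.33   # 150 g/L hemoglobin / 64458 g/mol
tissues:
  water:
    optical: {mus: [0.0, 0.0, 0.0], g: 0.9, n: 1.33}
    acoustic: {c: 1480.0, rho: 1000.0, alpha0: 0.0022, y: 2.0}
    functional: {blood_vf: 0.0, water_vf: 1.0, fat_vf: 0.0}
  epidermis:
    optical: {mus: [30.0, 28.0, 26.5], g: 0.9, n: 1.40}
    acoustic: {c: 1615.0, rho: 1090.0, alpha0: 0.8, y: 1.1}
    functional: {blood_vf: 0.0, water_vf: [0.4, 0.6], fat_vf: 0.0}
  dermis:
    optical: {mus: [20.0, 19.0, 18.0], g: 0.9, n: 1.40}
    acoustic: {c: 1610.0, rho: 1090.0, alpha0: 0.8, y: 1.1}
    functional: {blood_vf: [0.002, 0.005], water_vf: [0.5, 0.7], fat_vf: [0.1, 0.2], so2: [0.7, 0.85]}
  fat:
    optical: {mus: [10.5, 10.0, 9.5], g: 0.9, n: 1.44}
    acoustic: {c: [1430.0, 1470.0], rho: [900.0, 940.0], alpha0: [0.4, 0.8], y: 1.1}
    functional: {blood_vf: [0.003, 0.01], water_vf: [0.1, 0.2], fat_vf: [0.7, 0.9], so2: [0.7, 0.85]}
  fibroglandular:
    optical: {mus: [12.5, 12.0, 11.5], g: 0.9, n: 1.40}
    acoustic: {c: [1510.0, 1560.0], rho: [1020.0, 1060.0], alpha0: [0.5, 1.0], y: 1.5}
    functional: {blood_vf: [0.01, 0.03], water_vf: [0.5, 0.7], fat_vf: [0.1, 0.25], so2: [0.7, 0.85]}
  artery:
    optical: {mus: [10.0, 9.5, 9.0], g: 0.9, n: 1.40}
    acoustic: {c: [1570.0, 1590.0], rho: [1045.0, 1055.0], alpha0: 0.2, y: 1.2}
    functional: {blood_vf: 1.0, water_vf: 0.0, fat_vf: 0.0, so2: [0.92, 0.98]}
  vein:
    optical: {mus: [10.0, 9.5, 9.0], g: 0.9, n: 1.40}
    acoustic: {c: [1570.0, 1590.0], rho: [1045.0, 1055.0], alpha0: 0.2, y: 1.2}
    functional: {blood_vf: 1.0, water_vf: 0.0, fat_vf: 0.0, so2: [0.60, 0.80]}
  tumor_viable:
    optical: {mus: [12.0, 11.5, 11.0], g: 0.9, n: 1.40}
    acoustic: {c: [1540.0, 1570.0], rho: [1040.0, 1060.0], alpha0: [0.6, 1.0], y: 1.5}
    functional: {blood_vf: [0.03, 0.07], water_vf: [0.6, 0.8], fat_vf: [0.05, 0.15], so2: [0.50, 0.70]}
  tumor_necrotic:
    optical: {mus: [12.0, 11.5, 11.0], g: 0.9, n: 1.40}
    acoustic: {c: [1540.0, 1570.0], rho: [1040.0, 1060.0], alpha0: [0.6, 1.0], y: 1.5}
    functional: {blood_vf: [0.001, 0.004], water_vf: [0.6, 0.8], fat_vf: [0.05, 0.15], so2: [0.30, 0.50]}
  tumor_angiogenesis:
    optical: {mus: [12.0, 11.5, 11.0], g: 0.9, n: 1.40}
    acoustic: {c: [1540.0, 1570.0], rho: [1040.0, 1060.0], alpha0: [0.6, 1.0], y: 1.5}
    functional: {blood_vf: [0.04, 0.08], water_vf: [0.6, 0.8], fat_vf: [0.05, 0.15], so2: [0.55, 0.75]}
# Fitzpatrick skin tone -> epidermal melanosome volume fraction sampling range.
melanosome_vf_by_fitzpatrick:
  1: [0.010, 0.020]
  2: [0.020, 0.040]
  3: [0.040, 0.080]
  4: [0.080, 0.150]
  5: [0.150, 0.250]
  6: [0.250, 0.400]
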