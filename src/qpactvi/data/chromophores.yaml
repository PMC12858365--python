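# Specific absorption spectra of the chromophores used by the phantom generator
# and the spectral-unmixing estimators, at the three illumination wavelengths.
#
# Units:
#   HbO2, Hb   : mm^-1 per mM of hemoglobin (natural-log convention; the ln(10)
#                factor of the decadic molar extinction tables is folded in).
#   water, fat : mm^-1 per unit volume fraction.
#   melanin    : mm^-1 per unit melanosome volume fraction (interior-of-
#                melanosome absorption, ~lambda^-3.33 power law).
#
# Values are rounded from the widely used tissue-optics compilations
# (Prahl hemoglobin tables; Jacques' review for water/lipid/melanosome).
# Replace this file to substitute a different calibration.
version: 1
wavelengths_nm: [757, 800, 850]
epsilon:
  HbO2: [0.1359, 0.1879, 0.2437]
  Hb: [0.3662, 0.1755, 0.1591]
  water: [0.00262, 0.00220, 0.00430]
  fat: [0.00110, 0.00090, 0.00095]
  melanin: [16.9, 14.2, 11.6]
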