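# Experiment conditions for the reproduced crowding studies, one block per
# condition.  Printed-table values: pixels_per_degree, contrast_sigma_px,
# sigma_t and k_phi are the published derived columns and are recomputed
# (and checked) by radialcontrast.runner.reproduce_table1.
#
# PL and PS as printed are mutually inconsistent: their k_phi columns match
# the |E_alpha - mu_t| / (0.1 * mu_t) formula only if the two E_alpha
# entries are exchanged.  Both readings are kept; e_alpha_exchanged carries
# the swapped value and nothing guesses which was intended.
pixel_pitch_mm: 0.282
surround_ratio: 5        # K = sigma_B / sigma_F
collection_window_deg: 17.2  # width of the dendritic-data window around the
                             # region of interest; recorded, not used to vary
                             # sigma across an image
experiments:
  HE:
    family: vernier_lines
    eccentricity_deg: 3.88
    distance_cm: 75.00
    pixels_per_degree: 46.4177
    contrast_sigma_px: 0.5541
    mu_t: 0.020228
    sigma_t: 0.0006665
    e_alpha: 0.080
    k_phi: 29.5499
  KA:
    family: landolt_bars
    eccentricity_deg: 5.00
    distance_cm: 2300.00
    pixels_per_degree: 1423.4770
    contrast_sigma_px: 10.8793
    mu_t: 0.016057
    sigma_t: 0.0005291
    e_alpha: 0.032
    k_phi: 9.9290
  PA1:
    family: concentric_cs
    eccentricity_deg: 10.00
    distance_cm: 58.00
    pixels_per_degree: 35.8963
    contrast_sigma_px: 0.8324
    mu_t: 0.011640
    sigma_t: 0.0003835
    e_alpha: 0.030
    k_phi: 15.7745
  PA5:
    family: concentric_cs
    eccentricity_deg: 10.00
    distance_cm: 58.00
    pixels_per_degree: 35.8963
    contrast_sigma_px: 0.8324
    mu_t: 0.011640
    sigma_t: 0.0003835
    e_alpha: 0.080
    k_phi: 58.7319
  PL:
    family: letter_array
    eccentricity_deg: [5.00, 10.00, 15.00, 20.00]
    distance_cm: 55.88
    pixels_per_degree: 34.5843
    contrast_sigma_px: [0.4956, 0.7620, 1.0688, 1.4252]
    mu_t: 0.012000
    sigma_t: 0.0003954
    e_alpha: 0.010
    e_alpha_exchanged: 0.025
    k_phi: 10.8333
  PS:
    family: letter_array
    eccentricity_deg: [5.00, 10.00, 15.00, 20.00]
    distance_cm: 55.88
    pixels_per_degree: 34.5843
    contrast_sigma_px: [0.4956, 0.7620, 1.0688, 1.4252]
    mu_t: 0.005000
    sigma_t: 0.0001648
    e_alpha: 0.025
    e_alpha_exchanged: 0.010
    k_phi: 9.9999
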