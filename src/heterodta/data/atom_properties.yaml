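# Physico-chemical property table for the 27-symbol drug-atom vocabulary.
#
# SYNTHETIC STAND-IN: 9 elemental descriptors taken from standard periodic
# data.  UNK (the catch-all symbol) carries an all-zero row.  Fully editable;
# `columns` documents each descriptor in order.
columns:
  - atomic_number
  - atomic_mass_da
  - pauling_electronegativity
  - covalent_radius_A
  - vdw_radius_A
  - valence_electrons
  - period
  - first_ionization_eV
  - electron_affinity_eV
values:
  C:   [ 6,  12.011, 2.55, 0.76, 1.70, 4, 2, 11.26,  1.26]
  N:   [ 7,  14.007, 3.04, 0.71, 1.55, 5, 2, 14.53, -0.07]
  O:   [ 8,  15.999, 3.44, 0.66, 1.52, 6, 2, 13.62,  1.46]
  S:   [16,  32.06,  2.58, 1.05, 1.80, 6, 3, 10.36,  2.08]
  P:   [15,  30.974, 2.19, 1.07, 1.80, 5, 3, 10.49,  0.75]
  F:   [ 9,  18.998, 3.98, 0.57, 1.47, 7, 2, 17.42,  3.40]
  Cl:  [17,  35.45,  3.16, 1.02, 1.75, 7, 3, 12.97,  3.61]
  Br:  [35,  79.904, 2.96, 1.20, 1.85, 7, 4, 11.81,  3.36]
  I:   [53, 126.904, 2.66, 1.39, 1.98, 7, 5, 10.45,  3.06]
  B:   [ 5,  10.81,  2.04, 0.84, 1.92, 3, 2,  8.30,  0.28]
  Si:  [14,  28.085, 1.90, 1.11, 2.10, 4, 3,  8.15,  1.39]
  Se:  [34,  78.971, 2.55, 1.20, 1.90, 6, 4,  9.75,  2.02]
  As:  [33,  74.922, 2.18, 1.19, 1.85, 5, 4,  9.81,  0.80]
  H:   [ 1,   1.008, 2.20, 0.31, 1.20, 1, 1, 13.60,  0.75]
  Li:  [ 3,   6.94,  0.98, 1.28, 1.82, 1, 2,  5.39,  0.62]
  Na:  [11,  22.990, 0.93, 1.66, 2.27, 1, 3,  5.14,  0.55]
  K:   [19,  39.098, 0.82, 2.03, 2.75, 1, 4,  4.34,  0.50]
  Mg:  [12,  24.305, 1.31, 1.41, 1.73, 2, 3,  7.65, -0.40]
  Ca:  [20,  40.078, 1.00, 1.76, 2.31, 2, 4,  6.11,  0.02]
  Mn:  [25,  54.938, 1.55, 1.39, 2.05, 7, 4,  7.43, -0.50]
  Fe:  [26,  55.845, 1.83, 1.32, 2.04, 8, 4,  7.90,  0.15]
  Co:  [27,  58.933, 1.88, 1.26, 2.00, 9, 4,  7.88,  0.66]
  Ni:  [28,  58.693, 1.91, 1.24, 1.97, 10, 4, 7.64,  1.16]
  Cu:  [29,  63.546, 1.90, 1.32, 1.96, 11, 4, 7.73,  1.24]
  Zn:  [30,  65.38,  1.65, 1.22, 2.01, 12, 4, 9.39, -0.60]
  Sr:  [38,  87.62,  0.95, 1.95, 2.49, 2, 5,  5.69,  0.05]
  UNK: [ 0,   0.0,   0.0,  0.0,  0.0,  0, 0,  0.0,   0.0]
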