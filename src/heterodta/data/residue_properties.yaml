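# Physico-chemical property table for the 20 standard amino acids.
#
# SYNTHETIC STAND-IN: 24 per-residue descriptors assembled from widely used
# published scales (hydropathy, hydrophilicity, volume, polarity, charge,
# secondary-structure propensities, surface area, H-bonding capacity, ...).
# They are a reasonable, clearly labeled stand-in for any particular
# 24-property selection and are fully editable: rows are residues (one-letter
# code), `columns` documents the provenance of each descriptor in order.
columns:
  - kyte_doolittle_hydropathy
  - hopp_woods_hydrophilicity
  - eisenberg_hydrophobicity
  - fauchere_pliska_transfer_dG
  - molecular_weight_da
  - zamyatnin_volume_A3
  - zimmerman_bulkiness
  - grantham_polarity
  - zimmerman_polarity
  - isoelectric_point
  - net_charge_ph7
  - sidechain_pka
  - bhaskaran_flexibility
  - chou_fasman_helix
  - chou_fasman_sheet
  - chou_fasman_turn
  - max_accessible_surface_A2
  - janin_buried_fraction
  - aromatic_flag
  - aliphatic_flag
  - hbond_donor_count
  - hbond_acceptor_count
  - sidechain_heavy_atoms
  - jones_refractivity
values:
  A: [ 1.8, -0.5,  0.62,  0.31,  89.1,  88.6, 11.5,  8.1,  0.0,  6.00,  0.0,  0.0, 0.36, 1.42, 0.83, 0.66, 129.0, 0.74, 0, 1, 0, 0, 1,  4.34]
  C: [ 2.5, -1.0,  0.29,  1.54, 121.2, 108.5, 13.5,  5.5,  1.48, 5.07,  0.0,  8.3, 0.35, 0.70, 1.19, 1.19, 167.0, 0.91, 0, 0, 1, 0, 2, 35.77]
  D: [-3.5,  3.0, -0.90, -0.77, 133.1, 111.1, 11.7, 13.0, 49.7,  2.77, -1.0,  3.9, 0.51, 1.01, 0.54, 1.46, 193.0, 0.62, 0, 0, 1, 4, 4, 12.00]
  E: [-3.5,  3.0, -0.74, -0.64, 147.1, 138.4, 13.6, 12.3, 49.9,  3.22, -1.0,  4.1, 0.50, 1.51, 0.37, 0.74, 223.0, 0.62, 0, 0, 1, 4, 5, 17.26]
  F: [ 2.8, -2.5,  1.19,  1.79, 165.2, 189.9, 19.8,  5.2,  0.35, 5.48,  0.0,  0.0, 0.31, 1.13, 1.38, 0.60, 240.0, 0.88, 1, 0, 0, 0, 7, 29.40]
  G: [-0.4,  0.0,  0.48,  0.00,  75.1,  60.1,  3.4,  9.0,  0.0,  5.97,  0.0,  0.0, 0.54, 0.57, 0.75, 1.56, 104.0, 0.72, 0, 0, 0, 0, 0,  0.00]
  H: [-3.2, -0.5, -0.40,  0.13, 155.2, 153.2, 13.7, 10.4, 51.6,  7.59,  0.1,  6.0, 0.32, 1.00, 0.87, 0.95, 224.0, 0.78, 1, 0, 1, 1, 6, 21.81]
  I: [ 4.5, -1.8,  1.38,  1.80, 131.2, 166.7, 21.4,  5.2,  0.13, 6.02,  0.0,  0.0, 0.46, 1.08, 1.60, 0.47, 197.0, 0.88, 0, 1, 0, 0, 4, 19.06]
  K: [-3.9,  3.0, -1.50, -0.99, 146.2, 168.6, 15.7, 11.3, 49.5,  9.74,  1.0, 10.5, 0.47, 1.16, 0.74, 1.01, 236.0, 0.52, 0, 0, 2, 1, 5, 21.29]
  L: [ 3.8, -1.8,  1.06,  1.70, 131.2, 166.7, 21.4,  4.9,  0.13, 5.98,  0.0,  0.0, 0.37, 1.21, 1.30, 0.59, 201.0, 0.85, 0, 1, 0, 0, 4, 18.78]
  M: [ 1.9, -1.3,  0.64,  1.23, 149.2, 162.9, 16.3,  5.7,  1.43, 5.74,  0.0,  0.0, 0.30, 1.45, 1.05, 0.60, 224.0, 0.85, 0, 0, 0, 0, 4, 21.64]
  N: [-3.5,  0.2, -0.78, -0.60, 132.1, 114.1, 12.8, 11.6,  3.38, 5.41,  0.0,  0.0, 0.46, 0.67, 0.89, 1.56, 195.0, 0.63, 0, 0, 2, 2, 4, 13.28]
  P: [-1.6,  0.0,  0.12,  0.72, 115.1, 112.7, 17.4,  8.0,  1.58, 6.30,  0.0,  0.0, 0.51, 0.57, 0.55, 1.52, 159.0, 0.64, 0, 0, 0, 0, 3, 10.93]
  Q: [-3.5,  0.2, -0.85, -0.22, 146.2, 143.8, 14.5, 10.5,  3.53, 5.65,  0.0,  0.0, 0.49, 1.11, 1.10, 0.98, 225.0, 0.62, 0, 0, 2, 2, 5, 17.56]
  R: [-4.5,  3.0, -2.53, -1.01, 174.2, 173.4, 14.3, 10.5, 52.0, 10.76,  1.0, 12.5, 0.53, 0.98, 0.93, 0.95, 274.0, 0.64, 0, 0, 5, 3, 7, 26.66]
  S: [-0.8,  0.3, -0.18, -0.04, 105.1,  89.0,  9.5,  9.2,  1.67, 5.68,  0.0,  0.0, 0.51, 0.77, 0.75, 1.43, 155.0, 0.66, 0, 0, 1, 2, 2,  6.35]
  T: [-0.7, -0.4, -0.05,  0.26, 119.1, 116.1, 15.8,  8.6,  1.66, 5.60,  0.0,  0.0, 0.44, 0.83, 1.19, 0.96, 172.0, 0.70, 0, 0, 1, 2, 3, 11.01]
  V: [ 4.2, -1.5,  1.08,  1.22, 117.1, 140.0, 21.6,  5.9,  0.13, 5.96,  0.0,  0.0, 0.39, 1.06, 1.70, 0.50, 174.0, 0.86, 0, 1, 0, 0, 3, 13.92]
  W: [-0.9, -3.4,  0.81,  2.25, 204.2, 227.8, 21.7,  5.4,  2.10, 5.89,  0.0,  0.0, 0.31, 1.08, 1.37, 0.96, 285.0, 0.85, 1, 0, 1, 0, 10, 42.53]
  Y: [-1.3, -2.3,  0.26,  0.96, 181.2, 193.6, 18.0,  6.2,  1.61, 5.66,  0.0, 10.1, 0.42, 0.69, 1.47, 1.14, 263.0, 0.76, 1, 0, 1, 1, 8, 31.53]
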