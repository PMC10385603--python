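{
  "name": "Cu-64",
  "half_life_h": 12.7004,
  "branch_beta_plus": 0.174,
  "branch_beta_minus": 0.39,
  "branch_ec": 0.44,
  "mean_energy_np_mev": 0.126585,
  "mean_energy_photon_mev": 0.18418,
  "source_citation": "Half-life 12.7004 h (ICRP Publication 107). Non-penetrating energy = 0.390 x 0.1902 MeV (mean beta-) + 0.174 x 0.2782 MeV (mean beta+) + 0.004 MeV (Auger + conversion electrons), mean branch energies from ICRP-107/MIRD decay tables. Photon energy = 0.174 x 1.022 MeV (annihilation) + 0.00475 x 1.3458 MeV (gamma). Branch fractions stored exactly as printed (beta+ 17.4%, beta- 39.0%, EC 44%); their sum of 1.004 is kept without renormalization."
}
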