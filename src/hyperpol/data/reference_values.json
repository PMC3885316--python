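{
  "meta": {
    "description": "Printed reference values for uracil response properties in gas and water (PCM), CAM-B3LYP/aug-cc-pVDZ.",
    "units": {
      "mu": "D",
      "beta": "a.u.",
      "wavenumber": "cm^-1",
      "i_ir": "km/mol",
      "a_raman": "angstrom^4/amu",
      "hw": "a.u."
    }
  },
  "table1": {
    "gas": {
      "mu_x": 1.21,
      "mu_z": 4.41,
      "mu": 4.57,
      "mu_experiment": 3.87,
      "beta_xxx": 79.3,
      "beta_xyy": 19.5,
      "beta_xzz": 5.7,
      "beta_zxx": -106.5,
      "beta_zyy": -36.5,
      "beta_zzz": 78.2,
      "beta_x": 104.6,
      "beta_z": -64.8,
      "beta_vec": 123.0
    },
    "water": {
      "mu_x": 1.88,
      "mu_z": 5.96,
      "mu": 6.25,
      "beta_xxx": 183.9,
      "beta_xyy": 44.0,
      "beta_xzz": 24.6,
      "beta_zxx": -240.5,
      "beta_zyy": -56.4,
      "beta_zzz": 262.3,
      "beta_x": 252.5,
      "beta_z": -34.6,
      "beta_vec": 254.9
    }
  },
  "table2": {
    "gas": {
      "modes": [
        {"index": 4, "wavenumber": 411, "i_ir": 20, "a_raman": 1, "label": "tau_ring", "beta_vec": 11.5},
        {"index": 5, "wavenumber": 524, "i_ir": 22, "a_raman": 2, "label": "delta_ring", "beta_vec": 13.8},
        {"index": 11, "wavenumber": 783, "i_ir": 4, "a_raman": 22, "label": "delta_ring", "beta_vec": 10.6},
        {"index": 23, "wavenumber": 1523, "i_ir": 127, "a_raman": 11, "label": "nu_ring+delta_NH", "beta_vec": 12.5},
        {"index": 24, "wavenumber": 1711, "i_ir": 56, "a_raman": 30, "label": "nu_ring+delta_CH", "beta_vec": 10.4},
        {"index": 25, "wavenumber": 1802, "i_ir": 902, "a_raman": 58, "label": "nu_CO+delta_NH", "beta_vec": 57.8},
        {"index": 26, "wavenumber": 1828, "i_ir": 607, "a_raman": 29, "label": "nu_CO+delta_NH", "beta_vec": 32.4}
      ],
      "total_beta_v": 65.0,
      "dynamic_beta_e": 139.8
    },
    "water": {
      "modes": [
        {"index": 5, "wavenumber": 530, "i_ir": 45, "a_raman": 4, "label": "delta_ring", "beta_vec": 29.5},
        {"index": 23, "wavenumber": 1527, "i_ir": 236, "a_raman": 42, "label": "nu_ring+delta_NH", "beta_vec": 35.6},
        {"index": 24, "wavenumber": 1699, "i_ir": 159, "a_raman": 75, "label": "nu_ring+delta_CH", "beta_vec": 29.6},
        {"index": 25, "wavenumber": 1721, "i_ir": 2086, "a_raman": 115, "label": "nu_CO+delta_NH", "beta_vec": 127.2},
        {"index": 26, "wavenumber": 1769, "i_ir": 877, "a_raman": 116, "label": "nu_CO+delta_NH", "beta_vec": 70.9}
      ],
      "total_beta_v": 193.9,
      "dynamic_beta_e": 214.1
    }
  },
  "claims": {
    "beta_au_to_si": 3.206361e-53,
    "hw_max": 0.06563,
    "mu_increase_percent": 37.0,
    "static_beta_increase_percent": 110.0,
    "eope_dispersion_gas_percent": 13.7,
    "shg_dispersion_gas_percent": 61.5,
    "eope_dispersion_water_percent": -16.0,
    "shg_dispersion_water_percent": 15.5,
    "solvent_ratio_static": 2.1,
    "solvent_ratio_eope": 1.53,
    "solvent_ratio_shg": 1.48,
    "bv_over_be_gas": 0.46,
    "bv_over_be_water": 0.91,
    "nu25_share_gas_percent": 89.0,
    "nu26_share_gas_percent": 50.0,
    "nu25_solvation_increment": 69.4,
    "nu26_solvation_increment": 38.5,
    "crossing_hw_water": 0.045,
    "spectrum_fwhm_cm1": 10.0
  }
}
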