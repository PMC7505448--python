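{
  "_comment": "Default 'paper-like' plasma-EV composition setpoints for the synthetic-data generator. nmr_class_fractions are 31P-NMR mole fractions (PC-dominant, SM second, minor classes below the 3% quantifiability limit, no PS). ms_headgroup_weights and ms_species_profiles define the MS-visible species profile within each headgroup (lyso species fold into their parent headgroup); MS relative abundances are ionization-biased, so they are a separate ground truth from the NMR mole fractions.",
  "nmr_class_fractions": {
    "PC": 0.767,
    "SM": 0.203,
    "PE": 0.015,
    "LPC": 0.010,
    "PI": 0.005
  },
  "ms_headgroup_weights": {
    "PC": 0.58,
    "SM": 0.24,
    "PE": 0.10,
    "PI": 0.08
  },
  "ms_species_profiles": {
    "PC": {
      "PC 16:0/18:1": 0.28,
      "PC 16:0/16:0": 0.15,
      "LPC 16:0": 0.14,
      "PC 18:0/18:1": 0.06,
      "PC 16:0/18:2": 0.06,
      "PC 18:0/18:2": 0.06,
      "PC 16:0/20:4": 0.06,
      "PC 18:1/18:1": 0.05,
      "LPC 18:0": 0.05,
      "PC 16:0/22:6": 0.05,
      "PC 18:0/20:4": 0.04
    },
    "SM": {
      "SM d18:1/16:0": 0.35,
      "SM d18:1/19:0": 0.20,
      "SM d18:1/24:1": 0.18,
      "SM d18:1/22:0": 0.15,
      "SM d18:1/18:0": 0.12
    },
    "PE": {
      "LPE 18:0": 0.25,
      "LPE 16:0": 0.22,
      "PE 18:0/20:4": 0.20,
      "PE 16:0/18:1": 0.18,
      "PE 18:0/18:1": 0.15
    },
    "PI": {
      "LPI 18:0": 0.30,
      "PI 18:0/20:4": 0.28,
      "PI 16:0/18:1": 0.22,
      "PI 18:0/18:2": 0.20
    }
  },
  "noise_params": {
    "ms_ppm_jitter": 5.0,
    "ms_precursor_ppm_jitter": 2.0,
    "intensity_lognormal_sigma": 0.15,
    "nmr_snr": 100.0,
    "decoy_peak_rate": 0,
    "class_fraction_sigma": 0.03
  }
}
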