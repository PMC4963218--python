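{
  "LYS": {
    "basins": [
      {"name": "beta", "weight": 0.38, "phi": -120.0, "psi": 135.0, "sd": 22.0},
      {"name": "ppII", "weight": 0.14, "phi": -72.0, "psi": 150.0, "sd": 12.0},
      {"name": "alphaR", "weight": 0.42, "phi": -63.0, "psi": -42.0, "sd": 11.0},
      {"name": "alphaL", "weight": 0.06, "phi": 57.0, "psi": 45.0, "sd": 10.0}
    ],
    "chi_wells": [
      [{"angle": -60.0, "weight": 0.55, "sd": 9.0}, {"angle": 180.0, "weight": 0.32, "sd": 9.0}, {"angle": 60.0, "weight": 0.13, "sd": 9.0}],
      [{"angle": 180.0, "weight": 0.60, "sd": 10.0}, {"angle": -60.0, "weight": 0.22, "sd": 10.0}, {"angle": 60.0, "weight": 0.18, "sd": 10.0}],
      [{"angle": 180.0, "weight": 0.62, "sd": 10.0}, {"angle": -60.0, "weight": 0.20, "sd": 10.0}, {"angle": 60.0, "weight": 0.18, "sd": 10.0}],
      [{"angle": 180.0, "weight": 0.58, "sd": 10.0}, {"angle": -60.0, "weight": 0.22, "sd": 10.0}, {"angle": 60.0, "weight": 0.20, "sd": 10.0}]
    ]
  },
  "ARG": {
    "basins": [
      {"name": "beta", "weight": 0.36, "phi": -120.0, "psi": 135.0, "sd": 22.0},
      {"name": "ppII", "weight": 0.15, "phi": -72.0, "psi": 150.0, "sd": 12.0},
      {"name": "alphaR", "weight": 0.43, "phi": -63.0, "psi": -42.0, "sd": 11.0},
      {"name": "alphaL", "weight": 0.06, "phi": 57.0, "psi": 45.0, "sd": 10.0}
    ],
    "chi_wells": [
      [{"angle": -60.0, "weight": 0.55, "sd": 9.0}, {"angle": 180.0, "weight": 0.33, "sd": 9.0}, {"angle": 60.0, "weight": 0.12, "sd": 9.0}],
      [{"angle": 180.0, "weight": 0.60, "sd": 10.0}, {"angle": -60.0, "weight": 0.23, "sd": 10.0}, {"angle": 60.0, "weight": 0.17, "sd": 10.0}],
      [{"angle": 180.0, "weight": 0.55, "sd": 10.0}, {"angle": -65.0, "weight": 0.25, "sd": 10.0}, {"angle": 65.0, "weight": 0.20, "sd": 10.0}],
      [{"angle": 180.0, "weight": 0.55, "sd": 12.0}, {"angle": -90.0, "weight": 0.25, "sd": 12.0}, {"angle": 90.0, "weight": 0.20, "sd": 12.0}]
    ]
  },
  "SER": {
    "basins": [
      {"name": "beta", "weight": 0.33, "phi": -120.0, "psi": 140.0, "sd": 22.0},
      {"name": "ppII", "weight": 0.16, "phi": -72.0, "psi": 150.0, "sd": 12.0},
      {"name": "alphaR", "weight": 0.40, "phi": -64.0, "psi": -40.0, "sd": 11.0},
      {"name": "alphaL", "weight": 0.11, "phi": 58.0, "psi": 40.0, "sd": 11.0}
    ],
    "chi_wells": [
      [{"angle": 60.0, "weight": 0.47, "sd": 9.0}, {"angle": -60.0, "weight": 0.30, "sd": 9.0}, {"angle": 180.0, "weight": 0.23, "sd": 9.0}]
    ]
  },
  "THR": {
    "basins": [
      {"name": "beta", "weight": 0.42, "phi": -115.0, "psi": 135.0, "sd": 22.0},
      {"name": "ppII", "weight": 0.14, "phi": -72.0, "psi": 150.0, "sd": 12.0},
      {"name": "alphaR", "weight": 0.39, "phi": -64.0, "psi": -42.0, "sd": 11.0},
      {"name": "alphaL", "weight": 0.05, "phi": 58.0, "psi": 40.0, "sd": 10.0}
    ],
    "chi_wells": [
      [{"angle": 60.0, "weight": 0.50, "sd": 8.0}, {"angle": -60.0, "weight": 0.42, "sd": 8.0}, {"angle": 180.0, "weight": 0.08, "sd": 8.0}]
    ]
  },
  "ASN": {
    "basins": [
      {"name": "beta", "weight": 0.30, "phi": -115.0, "psi": 130.0, "sd": 22.0},
      {"name": "ppII", "weight": 0.14, "phi": -72.0, "psi": 150.0, "sd": 12.0},
      {"name": "alphaR", "weight": 0.42, "phi": -64.0, "psi": -40.0, "sd": 11.0},
      {"name": "alphaL", "weight": 0.14, "phi": 58.0, "psi": 40.0, "sd": 11.0}
    ],
    "chi_wells": [
      [{"angle": -60.0, "weight": 0.52, "sd": 9.0}, {"angle": 180.0, "weight": 0.30, "sd": 9.0}, {"angle": 60.0, "weight": 0.18, "sd": 9.0}],
      [{"angle": -40.0, "weight": 0.40, "sd": 20.0}, {"angle": 120.0, "weight": 0.35, "sd": 20.0}, {"angle": -120.0, "weight": 0.25, "sd": 20.0}]
    ]
  }
}
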