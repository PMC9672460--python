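{
  "compound": {
    "name": "salvianolic acid A",
    "molecular_weight": 494.45,
    "fraction_unbound_plasma": 0.05,
    "blood_to_plasma_ratio": 0.7,
    "acid_pKa": 2.9,
    "logP": 1.5
  },
  "tissues": [
    {
      "tissue_name": "lung",
      "volume": 0.5,
      "blood_flow": 390.0,
      "kp": 0.893440954309785,
      "pstc": 2.477081677021475,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "heart",
      "volume": 0.33,
      "blood_flow": 15.6,
      "kp": 0.893440954309785,
      "pstc": 1.8578112577661061,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "brain",
      "volume": 1.45,
      "blood_flow": 46.8,
      "kp": 0.33504035786616937,
      "pstc": 0.2477081677021475,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "adipose",
      "volume": 14.0,
      "blood_flow": 19.5,
      "kp": 0.22336023857744625,
      "pstc": 1.2385408385107375,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "muscle",
      "volume": 29.0,
      "blood_flow": 50.7,
      "kp": 0.6700807157323387,
      "pstc": 6.192704192553688,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "skin",
      "volume": 3.4,
      "blood_flow": 19.5,
      "kp": 0.6700807157323387,
      "pstc": 1.2385408385107375,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "bone",
      "volume": 10.0,
      "blood_flow": 15.6,
      "kp": 0.4467204771548925,
      "pstc": 1.2385408385107375,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "gut",
      "volume": 1.65,
      "blood_flow": 39.0,
      "kp": 1.005121073598508,
      "pstc": 2.477081677021475,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "spleen",
      "volume": 0.19,
      "blood_flow": 7.8,
      "kp": 1.005121073598508,
      "pstc": 0.6192704192553687,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "liver",
      "volume": 1.8,
      "blood_flow": 97.5,
      "kp": 3.3504035786616937,
      "pstc": 37.156225155322126,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "kidney",
      "volume": 0.31,
      "blood_flow": 66.30000000000001,
      "kp": 2.2336023857744625,
      "pstc": 6.192704192553688,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "reproductive",
      "volume": 0.05,
      "blood_flow": 0.975,
      "kp": 0.6700807157323387,
      "pstc": 0.12385408385107376,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "rest_of_body",
      "volume": 3.0,
      "blood_flow": 2.925,
      "kp": 0.6700807157323387,
      "pstc": 1.2385408385107375,
      "vascular_fraction": 0.05
    },
    {
      "tissue_name": "red_marrow",
      "volume": 1.4,
      "blood_flow": 7.8,
      "kp": 0.6700807157323387,
      "pstc": 1.2385408385107375,
      "vascular_fraction": 0.05
    }
  ],
  "transporters": [
    {
      "transporter_name": "OATP1B1",
      "vmax": 303324188.47930384,
      "km": 228.77709613036745,
      "direction": "uptake"
    },
    {
      "transporter_name": "P-gp",
      "vmax": 454986282.71895576,
      "km": 228.77709613036745,
      "direction": "efflux"
    }
  ],
  "cardiac_output": 390.0,
  "venous_volume": 3.5,
  "arterial_volume": 1.8,
  "systemic_linear_clearance": 0.0
}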