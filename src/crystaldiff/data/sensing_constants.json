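{
  "version": 1,
  "system": "Tb-mesoMOF single crystal loaded with vitamin B12 (cobalamin)",
  "constants": {
    "max_load_mg_per_mg": {
      "value": 0.33,
      "units": "mg guest per mg MOF",
      "note": "reported saturation load of vitamin B12 in Tb-mesoMOF; sets the maximum detectable amount per crystal mass"
    },
    "initial_uptake_rate_per_hr": {
      "value": 0.112,
      "units": "fraction of saturation per hour",
      "note": "reported initial uptake rate; the early uptake is close to linear, so a short measurement window suffices"
    },
    "detection_limit_ng_per_ml": {
      "value": 10.0,
      "units": "ng/mL",
      "note": "reported absorption-spectroscopy detection limit for released cobalamin"
    },
    "cage_diameters_nm": {
      "value": [3.9, 4.7],
      "units": "nm",
      "note": "the two mesoporous cage diameters of the framework"
    },
    "window_diameters_nm": {
      "value": [1.3, 1.7],
      "units": "nm",
      "note": "diameters of the windows interconnecting the cages"
    },
    "molecule_dims_nm": {
      "value": [1.41, 1.83, 1.14],
      "units": "nm",
      "note": "bounding-box dimensions of the cobalamin molecule"
    },
    "uptake_duration_min": {
      "value": 780.0,
      "units": "min",
      "note": "observed time for a ~100 um crystal to become fully infused"
    },
    "release_duration_min": {
      "value": 3000.0,
      "units": "min",
      "note": "observed duration of substantial release before the trace plateaus"
    }
  }
}
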