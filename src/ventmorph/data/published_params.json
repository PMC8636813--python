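{
  "version": 1,
  "description": "Published group-level parameters for the NPH / AD / HC morphometry cohorts: per-group means and SDs of the six linear indices, pre/post means for ELD responder groups (including the BVR-at-PC brain and ventricle components and 3D ventricular volume), mFI-11 comorbidity counts, and group sizes. These are the generative defaults for cohort simulation.",
  "cohort_n": 21,
  "responder_n": 9,
  "classic_n": 6,
  "rho_prepost": 0.9,
  "rho_measures": 0.5,
  "groups": {
    "NPH": {
      "n": 21,
      "measures": {
        "ei": [0.380, 0.053],
        "bci": [0.284, 0.027],
        "ca_deg": [57.1, 20.8],
        "z_evans": [0.448, 0.056],
        "bvr_ac": [0.678, 0.176],
        "bvr_pc": [0.835, 0.316]
      }
    },
    "AD": {
      "n": 21,
      "measures": {
        "ei": [0.286, 0.033],
        "bci": [0.186, 0.032],
        "ca_deg": [109.0, 15.1],
        "z_evans": [0.294, 0.037],
        "bvr_ac": [1.436, 0.257],
        "bvr_pc": [2.611, 0.964]
      }
    },
    "HC": {
      "n": 21,
      "measures": {
        "ei": [0.277, 0.028],
        "bci": [0.175, 0.025],
        "ca_deg": [106.4, 11.5],
        "z_evans": [0.273, 0.043],
        "bvr_ac": [1.589, 0.332],
        "bvr_pc": [3.281, 1.220]
      }
    },
    "NPH-Classic": {
      "n": 6,
      "measures": {
        "ei": [0.392, 0.0577],
        "bci": [0.287, 0.0261],
        "ca_deg": [67.1, 23.9],
        "z_evans": [0.436, 0.0588],
        "bvr_ac": [0.712, 0.158],
        "bvr_pc": [0.922, 0.356]
      }
    },
    "NPH-Complex": {
      "n": 15,
      "measures": {
        "ei": [0.373, 0.0534],
        "bci": [0.281, 0.0279],
        "ca_deg": [54.6, 18.6],
        "z_evans": [0.449, 0.0565],
        "bvr_ac": [0.674, 0.188],
        "bvr_pc": [0.814, 0.312]
      }
    }
  },
  "longitudinal": {
    "Responder": {
      "n": 9,
      "pre": {
        "ei": [0.402, 0.054],
        "bci": [0.291, 0.026],
        "ca_deg": [61.6, 21.0],
        "z_evans": [0.461, 0.061],
        "bvr_ac": [0.613, 0.172],
        "bvr_pc": [0.789, 0.361],
        "bvr_pc_brain_mm": [27.36, 5.583],
        "bvr_pc_ventricle_mm": [38.60, 0.490],
        "ventricular_volume_cm3": [160.56, 89.9]
      },
      "post": {
        "ei": [0.399, 0.045],
        "bci": [0.294, 0.028],
        "ca_deg": [61.3, 19.7],
        "z_evans": [0.460, 0.059],
        "bvr_ac": [0.616, 0.159],
        "bvr_pc": [0.773, 0.295],
        "bvr_pc_brain_mm": [27.12, 5.392],
        "bvr_pc_ventricle_mm": [38.22, 9.639],
        "ventricular_volume_cm3": [120.28, 39.0]
      }
    },
    "Non-Responder": {
      "n": 12,
      "pre": {
        "ei": [0.363, 0.048],
        "bci": [0.278, 0.027],
        "ca_deg": [53.8, 21.0],
        "z_evans": [0.438, 0.052],
        "bvr_ac": [0.726, 0.170],
        "bvr_pc": [0.869, 0.290],
        "bvr_pc_brain_mm": [29.58, 4.774],
        "bvr_pc_ventricle_mm": [35.68, 5.772],
        "ventricular_volume_cm3": [156.05, 77.5]
      },
      "post": {
        "ei": [0.360, 0.050],
        "bci": [0.274, 0.031],
        "ca_deg": [55.8, 21.1],
        "z_evans": [0.424, 0.049],
        "bvr_ac": [0.714, 0.216],
        "bvr_pc": [0.926, 0.269],
        "bvr_pc_brain_mm": [30.23, 4.335],
        "bvr_pc_ventricle_mm": [33.89, 5.260],
        "ventricular_volume_cm3": [114.16, 38.0]
      }
    }
  },
  "comorbidity_counts": {
    "hypertension": 17,
    "impaired_sensorium": 13,
    "diabetes_mellitus": 7,
    "adl_dependent": 6,
    "myocardial_infarction": 3,
    "pci_cardiac_surgery_angina": 3,
    "respiratory_disease": 2,
    "peripheral_vascular_disease": 1,
    "congestive_heart_failure": 0,
    "tia_cva": 0,
    "cva_with_deficit": 0
  },
  "frailty_table": {
    "responder": {"0-2": 4, ">=3": 5},
    "non_responder": {"0-2": 5, ">=3": 7},
    "classic": {"0-2": 3, ">=3": 3},
    "complex": {"0-2": 6, ">=3": 9}
  },
  "notes": [
    "The published responder pre-ELD ventricle SD (bvr_pc_ventricle_mm = 38.60 +/- 0.490) is inconsistent with neighbouring SDs (likely a typographical slip for ~4.90); it is kept verbatim here and flagged.",
    "cva_with_deficit is not broken out in the published comorbidity table; the combined cerebrovascular row maps to tia_cva and cva_with_deficit defaults to absent."
  ]
}
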