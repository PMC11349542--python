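{
 "arms": {
  "chemotherapy": {
   "ae_probabilities": {
    "anemia": {
     "base": 0.25,
     "distribution": "beta",
     "high": 0.31,
     "low": 0.19
    },
    "leukopenia": {
     "base": 0.09,
     "distribution": "beta",
     "high": 0.11,
     "low": 0.07
    },
    "neutropenia": {
     "base": 0.46,
     "distribution": "beta",
     "high": 0.58,
     "low": 0.35
    },
    "thrombocytopenia": {
     "base": 0.18,
     "distribution": "beta",
     "high": 0.23,
     "low": 0.14
    }
   },
   "arm_label": "chemotherapy",
   "drug_schedule": [
    {
     "drug": "gemcitabine",
     "max_cycles": null
    },
    {
     "drug": "cisplatin",
     "max_cycles": 8
    }
   ],
   "followup_mix": {
    "chemotherapy": {
     "base": 0.69,
     "distribution": "beta",
     "high": 0.86,
     "low": 0.52
    },
    "immunotherapy": {
     "base": 0.11,
     "distribution": "beta",
     "high": 0.14,
     "low": 0.08
    },
    "other": {
     "base": 0.15,
     "distribution": "beta",
     "high": 0.19,
     "low": 0.11
    },
    "targeted": {
     "base": 0.05,
     "distribution": "beta",
     "high": 0.06,
     "low": 0.04
    }
   }
  },
  "pembrolizumab": {
   "ae_probabilities": {
    "anemia": {
     "base": 0.24,
     "distribution": "beta",
     "high": 0.3,
     "low": 0.18
    },
    "leukopenia": {
     "base": 0.12,
     "distribution": "beta",
     "high": 0.15,
     "low": 0.09
    },
    "neutropenia": {
     "base": 0.47,
     "distribution": "beta",
     "high": 0.59,
     "low": 0.35
    },
    "thrombocytopenia": {
     "base": 0.16,
     "distribution": "beta",
     "high": 0.2,
     "low": 0.12
    }
   },
   "arm_label": "pembrolizumab",
   "drug_schedule": [
    {
     "drug": "pembrolizumab",
     "max_cycles": null
    },
    {
     "drug": "gemcitabine",
     "max_cycles": null
    },
    {
     "drug": "cisplatin",
     "max_cycles": 8
    }
   ],
   "followup_mix": {
    "chemotherapy": {
     "base": 0.75,
     "distribution": "beta",
     "high": 0.94,
     "low": 0.56
    },
    "immunotherapy": {
     "base": 0.09,
     "distribution": "beta",
     "high": 0.11,
     "low": 0.07
    },
    "other": {
     "base": 0.14,
     "distribution": "beta",
     "high": 0.18,
     "low": 0.11
    },
    "targeted": {
     "base": 0.02,
     "distribution": "beta",
     "high": 0.03,
     "low": 0.02
    }
   }
  }
 },
 "costs": {
  "ae_costs": {
   "anemia": {
    "base": 213.32,
    "distribution": "gamma",
    "high": 266.65,
    "low": 159.99
   },
   "leukopenia": {
    "base": 495.74,
    "distribution": "gamma",
    "high": 619.68,
    "low": 371.81
   },
   "neutropenia": {
    "base": 354.0,
    "distribution": "gamma",
    "high": 442.5,
    "low": 265.5
   },
   "thrombocytopenia": {
    "base": 1054.22,
    "distribution": "gamma",
    "high": 1317.78,
    "low": 790.67
   }
  },
  "followup_regimens": {
   "chemotherapy": [
    "oxaliplatin",
    "folinic_acid",
    "fluorouracil"
   ],
   "immunotherapy": [
    "pembrolizumab"
   ],
   "other": [
    "irinotecan",
    "capecitabine"
   ],
   "targeted": [
    "regorafenib"
   ]
  },
  "imaging_cost_pfs": {
   "base": 45.27,
   "distribution": "gamma",
   "high": 56.59,
   "low": 33.95
  },
  "per_cycle_drug_costs": {
   "capecitabine": {
    "base": 36.81,
    "distribution": "gamma",
    "high": 55.72,
    "low": 27.86
   },
   "cisplatin": {
    "base": 9.59,
    "distribution": "gamma",
    "high": 11.37,
    "low": 7.78
   },
   "fluorouracil": {
    "base": 39.36,
    "distribution": "gamma",
    "high": 366.46,
    "low": 28.82
   },
   "folinic_acid": {
    "base": 36.64,
    "distribution": "gamma",
    "high": 115.56,
    "low": 9.7
   },
   "gemcitabine": {
    "base": 92.96,
    "distribution": "gamma",
    "high": 106.85,
    "low": 72.11
   },
   "irinotecan": {
    "base": 338.62,
    "distribution": "gamma",
    "high": 1173.71,
    "low": 39.78
   },
   "oxaliplatin": {
    "base": 133.13,
    "distribution": "gamma",
    "high": 148.04,
    "low": 89.43
   },
   "pembrolizumab": {
    "base": 5324.82,
    "distribution": "gamma",
    "high": 6656.03,
    "low": 3993.62
   },
   "regorafenib": {
    "base": 1724.94,
    "distribution": "gamma",
    "high": 1834.56,
    "low": 1614.69
   }
  }
 },
 "settings": {
  "annual_discount_rate": 0.05,
  "country_label": "China",
  "cycle_days": 21,
  "days_per_month": 30.4375,
  "horizon_years": 10,
  "wtp_per_qaly": 38201.19
 },
 "survival": {
  "chemotherapy": {
   "os": {
    "family": "loglogistic",
    "params": {
     "scale": 10.8447,
     "shape": 1.8019
    }
   },
   "pfs": {
    "family": "lognormal",
    "params": {
     "meanlog": 1.6558,
     "sdlog": 1.0038
    }
   }
  },
  "pembrolizumab": {
   "os": {
    "family": "loglogistic",
    "params": {
     "scale": 12.6047,
     "shape": 1.7984
    }
   },
   "pfs": {
    "family": "lognormal",
    "params": {
     "meanlog": 1.7765,
     "sdlog": 1.109
    }
   }
  }
 },
 "utilities": {
  "ae_disutilities": {
   "anemia": {
    "base": -0.09,
    "distribution": "beta",
    "high": -0.07,
    "low": -0.11
   },
   "leukopenia": {
    "base": -0.2,
    "distribution": "beta",
    "high": -0.15,
    "low": -0.25
   },
   "neutropenia": {
    "base": -0.2,
    "distribution": "beta",
    "high": -0.15,
    "low": -0.25
   },
   "thrombocytopenia": {
    "base": -0.108,
    "distribution": "beta",
    "high": -0.08,
    "low": -0.13
   }
  },
  "u_pd": {
   "base": 0.69,
   "distribution": "beta",
   "high": 0.72,
   "low": 0.45
  },
  "u_pfs": {
   "base": 0.79,
   "distribution": "beta",
   "high": 0.8,
   "low": 0.6
  }
 }
}
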