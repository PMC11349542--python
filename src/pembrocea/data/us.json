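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
    "base": 81991.0,
    "distribution": "gamma",
    "high": 102488.75,
    "low": 61493.25
   },
   "leukopenia": {
    "base": 11648.0,
    "distribution": "gamma",
    "high": 14560.0,
    "low": 8736.0
   },
   "neutropenia": {
    "base": 17017.0,
    "distribution": "gamma",
    "high": 21271.25,
    "low": 12762.75
   },
   "thrombocytopenia": {
    "base": 9191.0,
    "distribution": "gamma",
    "high": 11488.75,
    "low": 6893.25
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
    "base": 226.12,
    "distribution": "gamma",
    "high": 307.41,
    "low": 144.82
   },
   "cisplatin": {
    "base": 23.45,
    "distribution": "gamma",
    "high": 30.61,
    "low": 16.28
   },
   "fluorouracil": {
    "base": 35.23,
    "distribution": "gamma",
    "high": 40.79,
    "low": 29.67
   },
   "folinic_acid": {
    "base": 82.11,
    "distribution": "gamma",
    "high": 95.2,
    "low": 69.02
   },
   "gemcitabine": {
    "base": 69.61,
    "distribution": "gamma",
    "high": 71.62,
    "low": 67.59
   },
   "irinotecan": {
    "base": 67.26,
    "distribution": "gamma",
    "high": 78.24,
    "low": 56.28
   },
   "oxaliplatin": {
    "base": 35.69,
    "distribution": "gamma",
    "high": 37.9,
    "low": 33.47
   },
   "pembrolizumab": {
    "base": 10933.1,
    "distribution": "gamma",
    "high": 11083.4,
    "low": 10782.8
   },
   "regorafenib": {
    "base": 2018.52,
    "distribution": "gamma",
    "high": 2467.71,
    "low": 1569.33
   }
  }
 },
 "settings": {
  "annual_discount_rate": 0.03,
  "country_label": "US",
  "cycle_days": 21,
  "days_per_month": 30.4375,
  "horizon_years": 10,
  "wtp_per_qaly": 229044.0
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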