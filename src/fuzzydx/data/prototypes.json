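{
 "comment": "Class-conditional prototypes for the synthetic cohort generator. Feature entries are [mean, sd] for truncated-normal draws inside the schema domain. Direction of separation per class: AD high FAQ/CDRSB with severe symptoms; CN high MMSE/MOCA with benign symptoms; LMCI elevated LDELTOTAL, RAVLT_perc_forgetting, ADAS13, Ventricles, TAU, PTAU; EMCI low FDG, MidTemp, Hippocampus; SMC near-normal numerics with low-grade memory-concern symptoms. Exact means/sds are synthetic design values, not estimates of any real cohort. Symptom/complication pools list [term, draw probability]; term severities come from the fixture taxonomy.",
 "classes": {
  "CN": {
   "features": {
    "CDRSB": [
     0.2,
     0.25
    ],
    "FAQ": [
     0.5,
     0.5
    ],
    "ADAS13": [
     6,
     1.5
    ],
    "MMSE": [
     29.3,
     0.5
    ],
    "MOCA": [
     28.2,
     0.7
    ],
    "FDG": [
     1.32,
     0.03
    ],
    "LDELTOTAL": [
     13,
     1.0
    ],
    "RAVLT_immediate": [
     45,
     4
    ],
    "RAVLT_perc_forgetting": [
     25,
     8
    ],
    "Hippocampus": [
     7400,
     250
    ],
    "MidTemp": [
     21000,
     700
    ],
    "Ventricles": [
     25000,
     4000
    ],
    "TAU": [
     200,
     25
    ],
    "PTAU": [
     18,
     2
    ],
    "AGE": [
     73,
     5
    ],
    "PTEDUCAT": [
     16,
     2
    ]
   },
   "apoe4_probs": [
    0.72,
    0.24,
    0.04
   ],
   "symptom_pool": [
    [
     "dry mouth",
     0.6
    ],
    [
     "light sweating",
     0.4
    ],
    [
     "urinary frequency",
     0.5
    ],
    [
     "knee pain",
     0.5
    ],
    [
     "headache",
     0.4
    ],
    [
     "constipation",
     0.4
    ]
   ],
   "complication_pool": [
    [
     "seasonal allergy",
     0.6
    ],
    [
     "topical dermatitis",
     0.5
    ]
   ],
   "severity_band": [
    0,
    2.5
   ]
  },
  "SMC": {
   "features": {
    "CDRSB": [
     0.3,
     0.3
    ],
    "FAQ": [
     1.0,
     0.8
    ],
    "ADAS13": [
     8,
     1.5
    ],
    "MMSE": [
     29.0,
     0.6
    ],
    "MOCA": [
     23,
     0.8
    ],
    "FDG": [
     1.25,
     0.03
    ],
    "LDELTOTAL": [
     9,
     1.0
    ],
    "RAVLT_immediate": [
     40,
     4
    ],
    "RAVLT_perc_forgetting": [
     35,
     8
    ],
    "Hippocampus": [
     7200,
     250
    ],
    "MidTemp": [
     20500,
     700
    ],
    "Ventricles": [
     28000,
     4000
    ],
    "TAU": [
     220,
     25
    ],
    "PTAU": [
     20,
     2
    ],
    "AGE": [
     72,
     5
    ],
    "PTEDUCAT": [
     16,
     2
    ]
   },
   "apoe4_probs": [
    0.65,
    0.3,
    0.05
   ],
   "symptom_pool": [
    [
     "memory concern",
     0.8
    ],
    [
     "forgetfulness",
     0.6
    ],
    [
     "misplacing items",
     0.5
    ],
    [
     "dry mouth",
     0.4
    ]
   ],
   "complication_pool": [
    [
     "seasonal allergy",
     0.5
    ],
    [
     "topical dermatitis",
     0.5
    ]
   ],
   "severity_band": [
    1,
    3.5
   ]
  },
  "EMCI": {
   "features": {
    "CDRSB": [
     2.5,
     0.5
    ],
    "FAQ": [
     3.0,
     1.0
    ],
    "ADAS13": [
     16,
     1.5
    ],
    "MMSE": [
     22,
     1.0
    ],
    "MOCA": [
     20,
     1.0
    ],
    "FDG": [
     1.0,
     0.03
    ],
    "LDELTOTAL": [
     13,
     1.0
    ],
    "RAVLT_immediate": [
     35,
     4
    ],
    "RAVLT_perc_forgetting": [
     55,
     8
    ],
    "Hippocampus": [
     5200,
     300
    ],
    "MidTemp": [
     17000,
     600
    ],
    "Ventricles": [
     35000,
     4000
    ],
    "TAU": [
     250,
     25
    ],
    "PTAU": [
     22,
     2
    ],
    "AGE": [
     72,
     5
    ],
    "PTEDUCAT": [
     16,
     2
    ]
   },
   "apoe4_probs": [
    0.55,
    0.35,
    0.1
   ],
   "symptom_pool": [
    [
     "anxious",
     0.7
    ],
    [
     "fearful",
     0.5
    ],
    [
     "suspicious",
     0.5
    ],
    [
     "can't sleep",
     0.4
    ]
   ],
   "complication_pool": [
    [
     "arterial hypertension",
     0.7
    ],
    [
     "high cholesterol",
     0.5
    ],
    [
     "osteoarthritis",
     0.4
    ]
   ],
   "severity_band": [
    3.0,
    5.5
   ]
  },
  "LMCI": {
   "features": {
    "CDRSB": [
     4.5,
     0.7
    ],
    "FAQ": [
     14,
     1.5
    ],
    "ADAS13": [
     30,
     2.5
    ],
    "MMSE": [
     17,
     1.2
    ],
    "MOCA": [
     18,
     1.2
    ],
    "FDG": [
     1.08,
     0.03
    ],
    "LDELTOTAL": [
     18,
     1.5
    ],
    "RAVLT_immediate": [
     30,
     4
    ],
    "RAVLT_perc_forgetting": [
     85,
     6
    ],
    "Hippocampus": [
     6200,
     250
    ],
    "MidTemp": [
     19500,
     700
    ],
    "Ventricles": [
     50000,
     5000
    ],
    "TAU": [
     320,
     25
    ],
    "PTAU": [
     28,
     2.5
    ],
    "AGE": [
     74,
     5
    ],
    "PTEDUCAT": [
     16,
     2
    ]
   },
   "apoe4_probs": [
    0.45,
    0.4,
    0.15
   ],
   "symptom_pool": [
    [
     "depressed mood",
     0.7
    ],
    [
     "confusion",
     0.6
    ],
    [
     "anxious",
     0.4
    ],
    [
     "occasional crying",
     0.3
    ]
   ],
   "complication_pool": [
    [
     "arterial hypertension",
     0.6
    ],
    [
     "sleep disorder",
     0.5
    ],
    [
     "diabetes",
     0.4
    ]
   ],
   "severity_band": [
    3,
    5.5
   ]
  },
  "AD": {
   "features": {
    "CDRSB": [
     10,
     1.5
    ],
    "FAQ": [
     23,
     2.0
    ],
    "ADAS13": [
     50,
     5
    ],
    "MMSE": [
     8,
     2
    ],
    "MOCA": [
     15,
     1.5
    ],
    "FDG": [
     0.9,
     0.05
    ],
    "LDELTOTAL": [
     2,
     1.0
    ],
    "RAVLT_immediate": [
     18,
     4
    ],
    "RAVLT_perc_forgetting": [
     92,
     5
    ],
    "Hippocampus": [
     4000,
     400
    ],
    "MidTemp": [
     15000,
     900
    ],
    "Ventricles": [
     60000,
     8000
    ],
    "TAU": [
     450,
     60
    ],
    "PTAU": [
     45,
     8
    ],
    "AGE": [
     75,
     5
    ],
    "PTEDUCAT": [
     14,
     2.5
    ]
   },
   "apoe4_probs": [
    0.3,
    0.45,
    0.25
   ],
   "symptom_pool": [
    [
     "memory loss",
     0.8
    ],
    [
     "disorientation",
     0.6
    ],
    [
     "difficulty in doing tasks involving multiple steps",
     0.6
    ],
    [
     "repetitive questioning",
     0.5
    ],
    [
     "trouble finding words",
     0.4
    ]
   ],
   "complication_pool": [
    [
     "pneumonia",
     0.5
    ],
    [
     "pressure ulcer",
     0.4
    ],
    [
     "malnutrition",
     0.5
    ],
    [
     "stroke",
     0.3
    ]
   ],
   "severity_band": [
    6.5,
    9.0
   ]
  }
 }
}
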