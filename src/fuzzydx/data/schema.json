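{
 "comment": "Default 68-feature schema: demographics (2), vital signs (2), genetics (1), cognitive scores (12), lab tests (42), MRI (7), PET (2). Cognitive, imaging and headline CSF/vitamin features follow ADNIMERGE naming; the remaining lab slots are a documented standard clinical chemistry/haematology panel and can be replaced wholesale by supplying a different schema file.",
 "features": [
  {"name": "AGE", "category": "demographics", "domain": [55, 91], "aliases": ["Age"]},
  {"name": "PTEDUCAT", "category": "demographics", "domain": [0, 20], "aliases": ["Education"]},

  {"name": "VSBPSYS", "category": "vital_signs", "domain": [70, 230], "aliases": ["Systolic_BP"]},
  {"name": "VSBPDIA", "category": "vital_signs", "domain": [40, 140], "aliases": ["Diastolic_BP"]},

  {"name": "APOE4", "category": "genetics", "domain": [0, 2], "kind": "singleton-ordinal"},

  {"name": "CDRSB", "category": "cognitive", "domain": [0, 18]},
  {"name": "ADAS11", "category": "cognitive", "domain": [0, 70]},
  {"name": "ADAS13", "category": "cognitive", "domain": [0, 85]},
  {"name": "MMSE", "category": "cognitive", "domain": [0, 30]},
  {"name": "MOCA", "category": "cognitive", "domain": [0, 30], "aliases": ["MoCA"]},
  {"name": "FAQ", "category": "cognitive", "domain": [0, 30]},
  {"name": "LDELTOTAL", "category": "cognitive", "domain": [0, 25]},
  {"name": "RAVLT_immediate", "category": "cognitive", "domain": [0, 75]},
  {"name": "RAVLT_learning", "category": "cognitive", "domain": [-5, 14]},
  {"name": "RAVLT_forgetting", "category": "cognitive", "domain": [-10, 15]},
  {"name": "RAVLT_perc_forgetting", "category": "cognitive", "domain": [0, 100]},
  {"name": "TRABSCOR", "category": "cognitive", "domain": [0, 300]},

  {"name": "ABETA", "category": "lab", "domain": [200, 1800]},
  {"name": "TAU", "category": "lab", "domain": [80, 1300]},
  {"name": "PTAU", "category": "lab", "domain": [8, 120]},
  {"name": "Glucose", "category": "lab", "domain": [40, 400]},
  {"name": "Sodium", "category": "lab", "domain": [120, 160]},
  {"name": "Potassium", "category": "lab", "domain": [2.5, 7]},
  {"name": "Chloride", "category": "lab", "domain": [85, 120]},
  {"name": "Bicarbonate", "category": "lab", "domain": [15, 40]},
  {"name": "BUN", "category": "lab", "domain": [3, 60]},
  {"name": "Creatinine", "category": "lab", "domain": [0.3, 5]},
  {"name": "Calcium", "category": "lab", "domain": [7, 12]},
  {"name": "Phosphorus", "category": "lab", "domain": [1.5, 6]},
  {"name": "Total_Protein", "category": "lab", "domain": [5, 10]},
  {"name": "Albumin", "category": "lab", "domain": [2.5, 6]},
  {"name": "Total_Bilirubin", "category": "lab", "domain": [0.1, 3]},
  {"name": "ALT", "category": "lab", "domain": [5, 200]},
  {"name": "AST", "category": "lab", "domain": [5, 200]},
  {"name": "ALP", "category": "lab", "domain": [20, 300]},
  {"name": "GGT", "category": "lab", "domain": [5, 300]},
  {"name": "LDH", "category": "lab", "domain": [80, 500]},
  {"name": "Total_Cholesterol", "category": "lab", "domain": [80, 400]},
  {"name": "HDL_Cholesterol", "category": "lab", "domain": [15, 120]},
  {"name": "LDL_Cholesterol", "category": "lab", "domain": [30, 300]},
  {"name": "Triglycerides", "category": "lab", "domain": [30, 800]},
  {"name": "Hemoglobin", "category": "lab", "domain": [8, 20]},
  {"name": "Hematocrit", "category": "lab", "domain": [25, 60]},
  {"name": "RBC_Count", "category": "lab", "domain": [3, 7]},
  {"name": "WBC_Count", "category": "lab", "domain": [2, 20]},
  {"name": "Platelets", "category": "lab", "domain": [50, 600]},
  {"name": "MCV", "category": "lab", "domain": [60, 120]},
  {"name": "MCH", "category": "lab", "domain": [20, 40]},
  {"name": "MCHC", "category": "lab", "domain": [28, 40]},
  {"name": "Vitamin_B12", "category": "lab", "domain": [100, 2000]},
  {"name": "Folate", "category": "lab", "domain": [1, 30]},
  {"name": "TSH", "category": "lab", "domain": [0.1, 15]},
  {"name": "Free_T4", "category": "lab", "domain": [0.4, 4]},
  {"name": "Uric_Acid", "category": "lab", "domain": [1.5, 12]},
  {"name": "CRP", "category": "lab", "domain": [0, 50]},
  {"name": "Homocysteine", "category": "lab", "domain": [3, 50]},
  {"name": "HbA1c", "category": "lab", "domain": [3.5, 15]},
  {"name": "Iron", "category": "lab", "domain": [10, 250]},
  {"name": "Ferritin", "category": "lab", "domain": [5, 1500]},

  {"name": "Ventricles", "category": "MRI", "domain": [5000, 160000]},
  {"name": "Hippocampus", "category": "MRI", "domain": [2000, 11000]},
  {"name": "WholeBrain", "category": "MRI", "domain": [600000, 1500000]},
  {"name": "Entorhinal", "category": "MRI", "domain": [1000, 6500]},
  {"name": "Fusiform", "category": "MRI", "domain": [8000, 30000]},
  {"name": "MidTemp", "category": "MRI", "domain": [5000, 32000]},
  {"name": "ICV", "category": "MRI", "domain": [1000000, 2200000]},

  {"name": "FDG", "category": "PET", "domain": [0.5, 2.0]},
  {"name": "AV45", "category": "PET", "domain": [0.6, 3.0]}
 ]
}
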