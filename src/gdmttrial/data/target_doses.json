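[
  {"drug_name": "enalapril", "drug_class": "ACE", "target_daily_dose_mg": 40},
  {"drug_name": "ramipril", "drug_class": "ACE", "target_daily_dose_mg": 10},
  {"drug_name": "perindopril", "drug_class": "ACE", "target_daily_dose_mg": 16},
  {"drug_name": "candesartan", "drug_class": "ARB", "target_daily_dose_mg": 32},
  {"drug_name": "valsartan", "drug_class": "ARB", "target_daily_dose_mg": 320},
  {"drug_name": "losartan", "drug_class": "ARB", "target_daily_dose_mg": 150},
  {"drug_name": "sacubitril/valsartan", "drug_class": "ARNI", "target_daily_dose_mg": 400},
  {"drug_name": "bisoprolol", "drug_class": "BETA_BLOCKER", "target_daily_dose_mg": 10},
  {"drug_name": "carvedilol", "drug_class": "BETA_BLOCKER", "target_daily_dose_mg": 50},
  {"drug_name": "metoprolol succinate", "drug_class": "BETA_BLOCKER", "target_daily_dose_mg": 200},
  {"drug_name": "nebivolol", "drug_class": "BETA_BLOCKER", "target_daily_dose_mg": 10},
  {"drug_name": "spironolactone", "drug_class": "MRA", "target_daily_dose_mg": 50},
  {"drug_name": "eplerenone", "drug_class": "MRA", "target_daily_dose_mg": 50},
  {"drug_name": "dapagliflozin", "drug_class": "SGLT2I", "target_daily_dose_mg": 10},
  {"drug_name": "empagliflozin", "drug_class": "SGLT2I", "target_daily_dose_mg": 10}
]
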