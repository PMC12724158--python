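{
 "rules": [
  {
   "rule_id": "recommended_dose_v1",
   "node_id": "recommended_dose",
   "file": "recommended_dose_v1.py",
   "sha256": "ef4a8b9e0a12c49c6f1c929b6e1736c7980c83de806d2e9942b1a0603d3431eb",
   "status": "verified",
   "guideline_text": "The recommended epinephrine dose for pediatric cardiac arrest is 0.01 mg per kg of body weight.",
   "signature": [
    [
     "patient_weight",
     "quantity"
    ]
   ]
  },
  {
   "rule_id": "dose_ratio_v1",
   "node_id": "dose_ratio",
   "file": "dose_ratio_v1.py",
   "sha256": "63510a6763c72d8c924cad34ac8ecc4e286b0d897632a40b0b69e43e31026576",
   "status": "verified",
   "guideline_text": "The dose ratio is the administered epinephrine dose divided by the weight-based recommended dose.",
   "signature": [
    [
     "administered_dose",
     "quantity"
    ],
    [
     "recommended_dose",
     "quantity"
    ]
   ]
  },
  {
   "rule_id": "classify_overdose_v1",
   "node_id": "overdose_ase",
   "file": "classify_overdose_v1.py",
   "sha256": "5b316fdc5862c0bcbb0678f0caeec4b60e8f516ed07568d5a72997a47516610c",
   "status": "verified",
   "guideline_text": "Administration of at least 2 times the recommended dose is a mild overdose; at least 10 times is severe.",
   "signature": [
    [
     "dose_ratio",
     "number"
    ]
   ]
  },
  {
   "rule_id": "classify_underdose_v1",
   "node_id": "underdose_ase",
   "file": "classify_underdose_v1.py",
   "sha256": "b159ad2544e58b8f804d27e44444b2f0606fa862e1b220232dece418f8236d39",
   "status": "verified",
   "guideline_text": "Administration of at most 80% of the recommended dose is a mild underdose; at most 50% is severe.",
   "signature": [
    [
     "dose_ratio",
     "number"
    ]
   ]
  },
  {
   "rule_id": "delay_from_arrival_v1",
   "node_id": "delay_from_arrival",
   "file": "delay_from_arrival_v1.py",
   "sha256": "baefae487c9a10cda4dd6c0ad3706299dad19abb5ffd2f5ff2ddace3d032cfbc",
   "status": "verified",
   "guideline_text": "Minutes elapsed from EMS scene arrival to the first epinephrine administration.",
   "signature": [
    [
     "first_epi_time",
     "timestamp"
    ],
    [
     "ems_arrival_time",
     "timestamp"
    ]
   ]
  },
  {
   "rule_id": "delay_from_arrest_v1",
   "node_id": "delay_from_arrest",
   "file": "delay_from_arrest_v1.py",
   "sha256": "8956b29cc074e8f9a493ace08b055bb5e45267f5b9c52c222dfb508070e2b98c",
   "status": "verified",
   "guideline_text": "Minutes elapsed from the beginning of cardiac arrest to the first epinephrine administration.",
   "signature": [
    [
     "first_epi_time",
     "timestamp"
    ],
    [
     "arrest_onset_time",
     "timestamp"
    ]
   ]
  },
  {
   "rule_id": "classify_delay_v1",
   "node_id": "delay_ase",
   "file": "classify_delay_v1.py",
   "sha256": "1c0d3cb0af3718ca40baa4a96210e57faef394d6580364b62b66f04b0fbd2d6a",
   "status": "verified",
   "guideline_text": "A first epinephrine dose given at least 5 minutes after both EMS arrival and arrest onset is a mild delay; at least 10 minutes after both is severe.",
   "signature": [
    [
     "delay_from_arrival",
     "quantity"
    ],
    [
     "delay_from_arrest",
     "quantity"
    ]
   ]
  }
 ]
}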