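# Weight-based recommended epinephrine dose: 0.01 mg per kg (PALS).
def rule(patient_weight):
    if patient_weight is None or patient_weight <= 0:
        raise ValueError("patient weight must be positive (kg)")
    return 0.01 * patient_weight
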