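# Administered-to-recommended dose ratio (dimensionless), both in mg.
def rule(administered_dose, recommended_dose):
    if recommended_dose is None or recommended_dose <= 0:
        raise ValueError("recommended dose must be positive (mg)")
    if administered_dose is None or administered_dose < 0:
        raise ValueError("administered dose must be non-negative (mg)")
    return administered_dose / recommended_dose
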