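# Underdose severity: severe at <= 50% of the recommended dose, mild at <= 80%.
# A zero dose is non-administration, not an underdose, and is rejected.
REL_TOL = 1e-9


def rule(dose_ratio):
    if dose_ratio <= 0:
        raise ValueError("a zero dose is non-administration, not an underdose")
    if dose_ratio <= 0.5 * (1.0 + REL_TOL):
        return "severe"
    if dose_ratio <= 0.8 * (1.0 + REL_TOL):
        return "mild"
    return "none"
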