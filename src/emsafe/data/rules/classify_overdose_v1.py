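# Overdose severity: severe at >= 10x the recommended dose, mild at >= 2x.
# A relative tolerance keeps ratios computed as 9.999999999.../10.000000001
# from misclassifying exact decimal-shift (10x) errors at the boundary.
REL_TOL = 1e-9


def rule(dose_ratio):
    if dose_ratio < 0:
        raise ValueError("dose ratio must be non-negative")
    if dose_ratio >= 10.0 * (1.0 - REL_TOL):
        return "severe"
    if dose_ratio >= 2.0 * (1.0 - REL_TOL):
        return "mild"
    return "none"
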