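# Delay severity. Both clocks must exceed the threshold ("given >= N minutes
# after (1) EMS arrival and (2) beginning of cardiac arrest"), which is
# equivalent to thresholding the minimum of the two elapsed times.
ABS_TOL = 1e-9


def rule(delay_from_arrival, delay_from_arrest):
    effective = min(delay_from_arrival, delay_from_arrest)
    if effective >= 10.0 - ABS_TOL:
        return "severe"
    if effective >= 5.0 - ABS_TOL:
        return "mild"
    return "none"
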