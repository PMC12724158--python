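# Minutes from arrest onset to the first epinephrine dose.
def rule(first_epi_time, arrest_onset_time):
    minutes = (first_epi_time - arrest_onset_time).total_seconds() / 60.0
    if minutes < 0:
        raise ValueError("first epinephrine dose precedes arrest onset (data-quality error)")
    return minutes
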