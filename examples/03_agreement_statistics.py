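"""Inter-rater agreement: Gwet's AC1 vs Cohen's kappa at low prevalence.

Two reviewers rate 100 charts for a rare event; they agree on 95. Kappa's
chance correction uses the product of the raters' marginals, which explodes
as the positive class becomes rare — the "kappa paradox". AC1's correction
stays stable, which is why it is the preferred coefficient for rare adverse
safety events.
"""
from emsafe import RatingTable, cohen_kappa, gwet_ac1

print("raw agreement fixed at 0.95; positive cases shrink left to right\n")
print(f"{'both-yes':>9s} {'prevalence':>11s} {'AC1':>7s} {'kappa':>7s}")
for both_yes in (30, 15, 5, 1):
    table = RatingTable.from_counts_2x2(both_yes, 3, 2, 95 - both_yes)
    prev = (2 * both_yes + 3 + 2) / (2 * table.n_items)
    print(f"{both_yes:9d} {prev:11.3f} {gwet_ac1(table):7.3f} {cohen_kappa(table):7.3f}")

# AC1 stays near the raw agreement while kappa collapses toward zero even
# though the raters never became less reliable — only the event got rarer.
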