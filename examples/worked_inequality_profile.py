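"""Full inequality profile of a small metric distribution.

Builds the three-component distribution (360, 250, 150) and its two-way
split (180, 180, 125, 125, 75, 75), computes the deviation-model measures
plus HHI, Theil and Atkinson, and shows that the uncorrected Gini is
blind to the split (identical relative structure) while the corrected
forms respond to the different component counts.
"""

import ineqkit as iq

a = iq.make_distribution([360, 250, 150])
b = iq.make_distribution([180, 180, 125, 125, 75, 75])

print("distribution A =", a.units.tolist(), f"(k={a.k}, N={a.total:.0f})")
print("distribution B =", b.units.tolist(), f"(k={b.k}, N={b.total:.0f})")
print()
print(f"{'measure':<18}{'A':>10}{'B':>10}")
for name, fn in [
    ("gini", iq.gini),
    ("gini_corrected", iq.gini_corrected),
    ("hoover", iq.hoover),
    ("rosenbluth", iq.rosenbluth),
    ("hhi", iq.hhi),
    ("theil", iq.theil),
    ("atkinson(eps=1)", lambda d: iq.atkinson(d, 1.0)),
]:
    print(f"{name:<18}{fn(a):>10.5f}{fn(b):>10.5f}")

print()
print("The uncorrected Gini and Hoover agree across A and B: splitting every")
print("component in two leaves the share structure unchanged.  The corrected")
print("forms and the Rosenbluth index differ because they depend on k.")
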