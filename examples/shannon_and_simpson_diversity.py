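"""Diversity of categorical data: Shannon and Simpson families.

Tabulates letter strings into category counts and prints the Shannon
index (bits of information per letter) and the Simpson-family
probabilities, illustrating the small-N gap between the with-replacement
HHI and the exact without-replacement Simpson index.
"""

import warnings

import ineqkit as iq

for text in ("AAAA", "ABCD", "AABBCCDD", "AAAB"):
    d = iq.counts_from_labels(text)
    si = iq.shannon(d, base=2)
    print(f"{text!r:12} k={d.k}  Shannon = {si:.4f} bits")
print()
print("0 bits: every letter is certain; 2 bits: two yes/no questions")
print("identify each of four equally likely letters.  Duplicating every")
print("letter changes nothing.")
print()

counts = iq.make_distribution([2, 2], kind="categorical")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # small-N advisory for HHI
    print("counts (2, 2):")
    print(f"  Simpson S            = {iq.simpson(counts):.5f}  "
          "(exact same-component pair probability, 2 of 6 pairs)")
    print(f"  Gini-Simpson 1-S     = {iq.gini_simpson(counts):.5f}")
    print(f"  inverse Simpson 1/S  = {iq.inverse_simpson(counts):.5f}")
    print(f"  HHI (with replacem.) = {iq.hhi(counts):.5f}  "
          "(overstates S at this tiny N)")
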