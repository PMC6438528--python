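"""Comparing correlation coefficients with the Fisher r-to-z test.

The segment-level analyses contrast how strongly different EEG scores
correlate with the same audience variable (n = 49 segments each).  This
example recomputes those contrasts from the correlation coefficients alone.
"""

from neuroaudience import fisher_z_difference

contrasts = [
    ("viewership: attention (r=0.74) vs asymmetry (r=0.14)", 0.74, 0.14),
    ("viewership: attention (r=0.74) vs memory (r=0.07)", 0.74, 0.07),
    ("asymmetry: twitter (r=0.44) vs viewership (r=0.14)", 0.44, 0.14),
    ("twitter: attention (r=0.48) vs memory (r=0.23)", 0.48, 0.23),
]

for label, r1, r2 in contrasts:
    res = fisher_z_difference(r1, 49, r2, 49)
    one = fisher_z_difference(r1, 49, r2, 49, tails="one")
    print(f"{label}: z = {res.z:.2f}, two-tailed p = {res.p:.4f} "
          f"(one-tailed p = {one.p:.4f})")

print("\nz above ~1.96 means the two correlations differ at the two-tailed "
      "5% level; the attention score's advantage over the other scores for "
      "viewership is decisive, while the asymmetry score's preference for "
      "Twitter over viewership is a one-tailed effect.")
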