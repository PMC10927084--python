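"""Random-population scan: mechanism composition of EAD-positive samples.

Draws 100 parameter sets with the five scaling factors log-uniform in
[0.1, 10], classifies each, and prints the mechanism composition among
the EAD-positive samples (use n=500+ for stable fractions).
"""
from eadkit.scans import monte_carlo

res = monte_carlo(n=100, seed=1)
print(f"EAD-positive: {res.n_ead_positive}/{res.n_samples}")
for label, frac in res.fractions.items():
    print(f"  {label:8s}: {100*frac:5.1f}% of EAD-positive samples")
print("(typeII+typeIV = Ca-cycling dependent mechanisms)")
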