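"""Encode residue-centred fragments into the 129-dimensional feature vector.

Each residue becomes the center of a length-9 window; the window is encoded
as 37 composition frequencies, 90 position-weight-matrix log-odds scores
(positive- and negative-trained matrices over 5 annotation tracks), and 2
physicochemical Shannon entropies.
"""

from metalbind import (PWMSet, encode_fragments, extract_all, feature_names,
                       worked_example)

chains = worked_example()            # fixed 3-chain fixture
fragments = extract_all(chains, L=9)
pwms = PWMSet.fit(fragments, background="empirical")
X, y = encode_fragments(fragments, pwms)

names = feature_names(9)
print(f"fragments encoded: {X.shape[0]}  (one per residue)")
print(f"feature dimension: {X.shape[1]}")
print(f"first/last names:  {names[0]} ... {names[-1]}")
print(f"positives:         {int(y.sum())} of {len(y)}")
v = X[0]
print(f"composition block sums to {v[:37].sum():.1f} (5 tracks x 1.0 each)")
print(f"entropies of fragment 0:  hydropathy {v[127]:.3f}, charge {v[128]:.3f}")
# Composition frequencies are exact window counts / 9; entropy is bounded by
# log2(6) and log2(3) for the 6 hydropathy and 3 charge classes.
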