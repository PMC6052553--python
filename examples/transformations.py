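"""Log-ratio transformations on a toy composition.

Builds a 6-feature composition, applies clr / iqlr / malr, and shows the
property that makes these transforms work for sequencing data: multiplying a
sample by any constant (a library-size change) leaves the result untouched.
"""

import numpy as np

import codadiff as cd

x = np.array([10.0, 20.0, 40.0, 40.0, 40.0, 250.0])

clr_ref = cd.ReferenceSet(np.arange(x.size), "all")
clr = cd.transform(x, clr_ref)
print("composition:      ", x)
print("clr(x):           ", clr.round(3))
print("clr sum (always 0):", round(clr.sum(), 12))

# denominator restricted to the three stable mid-range features
malr_ref = cd.ReferenceSet(np.array([2, 3, 4]), "user")
print("malr(x), ref 2-4: ", cd.transform(x, malr_ref).round(3))

# scale invariance: 'sequencing the sample 7x deeper' changes nothing
print("clr(7x) == clr(x):", np.allclose(cd.transform(7 * x, clr_ref), clr))

# iqlr on a count matrix: the wildly variable feature is excluded from
# the denominator reference
rng = np.random.default_rng(0)
values = rng.poisson(100, size=(6, 8))
values[5] = rng.poisson([5, 900] * 4)  # feature 5 swings two orders of magnitude
counts = cd.CountMatrix(values, [f"gene{i}" for i in range(6)], [f"s{j}" for j in range(8)])
ref = cd.select_iqlr_reference(counts)
print("iqlr reference indices (feature 5 excluded):", ref.indices)
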