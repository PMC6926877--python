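"""The separation detector on hand-built datasets.

Complete separation (a threshold splits the outcomes), overlap (no
separation), and quasi-complete separation (one covariate level is pure),
each certified by the returned direction vector.
"""

import numpy as np

import firthiss as fi

cases = {
    "ordered continuous": (np.array([[1.0], [2.0], [3.0], [4.0]]), np.array([0, 0, 1, 1])),
    "full overlap": (np.array([[0.0], [0.0], [1.0], [1.0]]), np.array([0, 1, 0, 1])),
    "pure level": (np.array([[0.0], [0.0], [0.0], [1.0], [1.0]]), np.array([0, 0, 1, 1, 1])),
}
for name, (X, y) in cases.items():
    rep = fi.detect_separation((X, y))
    print(f"{name:20s}: {rep.kind:15s} direction={rep.direction}")

# The direction b certifies the report: (2y-1) * (b . [1, x]) >= 0 for every
# row, strictly for all rows iff the separation is complete.
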