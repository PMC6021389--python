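"""Supervised CAIM discretization of one biomarker against CDR severity.

Builds a small class-labelled sample, runs the greedy CAIM search, and
shows the chosen cut points, the achieved criterion value and the quanta
matrix behind it.
"""

import numpy as np

from adbn import build_quanta_matrix, caim_discretize, caim_score
from adbn.discretize import apply_scheme, fixed_scheme

rng = np.random.default_rng(0)
# cerebrospinal-fluid-like volumes rising with severity
values = np.concatenate([
    rng.normal(280, 30, 80),    # normal
    rng.normal(330, 30, 40),    # very mild
    rng.normal(380, 30, 15),    # mild/moderate
])
classes = np.array(["normal"] * 80 + ["very mild"] * 40
                   + ["mild/moderate"] * 15)

scheme = caim_discretize(values, classes, max_intervals=3,
                         feature="csf_volume")
print("cut points:", np.round(scheme.cut_points, 1))
print("achieved CAIM:", round(scheme.achieved_caim, 2))

q = build_quanta_matrix(values, classes, scheme.cut_points)
print("quanta matrix (classes x intervals):")
print(q.counts)
print("criterion recomputed:", round(caim_score(q), 2))

cdr = fixed_scheme("cdr")
print("\nfixed CDR map:", apply_scheme([0.0, 0.5, 1.0, 2.0], cdr))
print(
    "\nThe two cuts separate the class-conditional volume ranges; a higher\n"
    "CAIM value means intervals are dominated by single severity classes."
)
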