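"""Two-time-point Bayesian networks and their structural diff.

Group 2 keeps the subjects complete at baseline and at least one later
visit, learns one network per time slice over the same feature set
(ApoE dropped: it cannot change within a subject), and compares the two
structures edge by edge.
"""

from adbn import CohortSimSpec, PipelineConfig, generate_cohort
from adbn.pipeline import run_longitudinal_experiment

table = generate_cohort(CohortSimSpec(
    n_subjects=900, seed=8,
    visit_retention={"M18": 0.75, "M36": 0.6, "M54": 0.5},
))
out = run_longitudinal_experiment(
    table, PipelineConfig(seed=8, folds=3, score="bic"), group=2,
)

print("features (ApoE excluded):", out["features"])
for name in ("baseline", "later"):
    r = out[name]["report"]
    print(f"{name:9s} n={out[name]['n_rows']:4d} "
          f"edges={out[name]['n_edges']} "
          f"MCA={r['mca']:.2f} AUC={r['auc']:.2f}")
diff = out["diff"]
print("edges added at later time:   ", diff["added"])
print("edges removed at later time: ", diff["removed"])
print("edges reversed:              ", diff["reversed"])
print(
    "\nWith both slices drawn from the same generating process, the diff\n"
    "contains only weak-edge churn; an injected dependency change would\n"
    "surface as a specific added or reversed edge."
)
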