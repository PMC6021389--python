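"""Entropy-based feature selection on a synthetic cohort with known ground
truth.

Eight features genuinely depend on CDR severity (age, ApoE, GM, CSF,
PiB-PET, MMSE, LMIR, LMDR); the other 24 are noise. Ten-fold
cross-validated ranking under information gain, gain ratio and symmetrical
uncertainty should keep exactly the informative eight at 100% selection
frequency.
"""

from adbn import CohortSimSpec, generate_cohort, select_features
from adbn.discretize import apply_schemes, learn_schemes
from adbn.simulate import INFORMATIVE_FEATURES

no_missing = {k: 0.0 for k in (
    "gm_volume", "wm_volume", "csf_volume", "pib_pet_voxels",
    "mmse", "lmir", "lmdr", "apoe")}
table = generate_cohort(CohortSimSpec(n_subjects=1500, seed=3,
                                      missing_rates=no_missing,
                                      missing_rate_default=0.0))
df = table.df.reset_index(drop=True)
disc = apply_schemes(df, learn_schemes(df, table.dictionary))

features = [s.name for s in table.dictionary if s.name != "cdr"]
report = select_features(disc, features, disc["cdr"].to_numpy(),
                         folds=10, keep=8, seed=1)

print("stable feature set (100% of folds):")
for f in report.final_set:
    print(f"  {f}")
print("planted informative set:", sorted(INFORMATIVE_FEATURES))
print("match:", report.final_set == sorted(INFORMATIVE_FEATURES))
print(
    "\nSelection frequency of 100% means the feature survived the median-\n"
    "rank filter consensus in every fold; noise features fail the G^2\n"
    "independence gate and never stabilize."
)
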