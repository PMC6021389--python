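"""Synthetic AIBL-like cohorts with known ground truth.

Two generators are provided:

* :func:`generate_cohort` emulates the raw cohort table: subject-visit rows
  over the full 33-feature dictionary, CDR drawn per subject from a class
  prevalence (with optional per-visit progression drift), eight informative
  features drawn conditionally on CDR (age, ApoE, GM, CSF, PiB-PET, MMSE,
  LMIR, LMDR), the remaining predictors as independent noise, clinical
  diagnosis generated as a noisy relabelling of the CDR category, and
  per-feature missingness masks mimicking the sparser imaging follow-up.

* :func:`sample_from_network` forward-samples (ancestral sampling in
  topological order) a discrete ground-truth Bayesian network, whose
  default topology mirrors the learned dependency structure: age and ApoE
  drive the imaging biomarkers, the biomarkers drive CDR severity, and CDR
  drives the cognitive assessments with deliberately stronger links.

Randomness: one master seed per run, split into named substreams, so
adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import BayesianNetworkModel
from .cohort import CohortTable
from .dictionary import APOE_GENOTYPES, FeatureSpec, default_dictionary
from .errors import GraphError, ValidationError

#: CDR classes present in the simulated cohorts (no severe cases).
SIM_CDR_CLASSES = (0.0, 0.5, 1.0, 2.0)

#: The eight CDR-informative features the pipeline should recover.
INFORMATIVE_FEATURES = (
    "age", "apoe", "gm_volume", "csf_volume", "pib_pet_voxels",
    "mmse", "lmir", "lmdr",
)


def substream_seed(seed: int, name: str) -> int:
    """Derive an independent substream seed from a master seed and a name."""
    h = hashlib.sha256(f"{seed}|{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# raw-cohort generator


#: Per-CDR-class Gaussian parameters (mean per class 0/0.5/1/2, sd).
DEFAULT_CONTINUOUS_MODELS = {
    "age": {"means": (70.0, 73.0, 75.0, 78.0), "sds": (7.0,) * 4},
    "mmse": {"means": (28.5, 26.5, 20.0, 14.0), "sds": (1.5, 2.0, 3.0, 4.0),
             "clip": (0.0, 30.0)},
    "lmir": {"means": (12.0, 8.0, 4.0, 2.0), "sds": (3.0,) * 4,
             "clip": (0.0, None)},
    "lmdr": {"means": (11.0, 6.0, 2.0, 0.5), "sds": (3.0,) * 4,
             "clip": (0.0, None)},
    "gm_volume": {"means": (620.0, 600.0, 570.0, 550.0), "sds": (40.0,) * 4},
    "csf_volume": {"means": (280.0, 310.0, 345.0, 370.0), "sds": (35.0,) * 4},
    "pib_pet_voxels": {"means": (300.0, 900.0, 1600.0, 2000.0),
                       "sds": (350.0,) * 4, "clip": (0.0, None)},
}

#: Per-CDR-class ApoE genotype probabilities (epsilon-4 load rises with
#: severity).
DEFAULT_APOE_MODEL = (
    (0.10, 0.62, 0.02, 0.23, 0.03),
    (0.07, 0.50, 0.03, 0.32, 0.08),
    (0.04, 0.38, 0.04, 0.40, 0.14),
    (0.04, 0.35, 0.04, 0.40, 0.17),
)

#: Class-independent noise models for the remaining predictors.
DEFAULT_NOISE_CONTINUOUS = {
    "hemoglobin": (140.0, 12.0),
    "glucose": (5.5, 1.0),
    "cholesterol_total": (5.2, 1.0),
    "hdl": (1.5, 0.4),
    "ldl": (3.0, 0.9),
    "triglycerides": (1.4, 0.6),
    "vitamin_b12": (300.0, 90.0),
    "folate": (20.0, 6.0),
    "creatinine": (80.0, 15.0),
    "urea": (6.0, 1.5),
    "albumin": (42.0, 3.0),
    "platelets": (250.0, 60.0),
    "wm_volume": (480.0, 40.0),
}

DEFAULT_FLAG_RATES = {
    "hypertension": 0.40, "diabetes": 0.10, "hypercholesterolemia": 0.35,
    "stroke": 0.05, "depression": 0.15, "head_injury": 0.08,
    "smoking": 0.30, "cardiovascular_disease": 0.20,
    "thyroid_disorder": 0.10, "neurological_disorder": 0.07,
}

#: Sparser follow-up of imaging, mirroring a realistic modality mix.
DEFAULT_MISSING_RATES = {
    "gm_volume": 0.25, "wm_volume": 0.25, "csf_volume": 0.25,
    "pib_pet_voxels": 0.55,
    "mmse": 0.02, "lmir": 0.04, "lmdr": 0.04,
    "apoe": 0.02,
}
DEFAULT_MISSING_RATE_OTHER = 0.02

#: Probability that the clinical diagnosis matches the CDR category;
#: mismatches move to an adjacent category. Chosen so the diagnosis-CDR
#: Pearson correlation is about 0.8 on integer codes.
DEFAULT_DIAGNOSIS_AGREEMENT = 0.86


@dataclass
class CohortSimSpec:
    """Conditions of a simulated cohort run."""

    n_subjects: int = 861
    visit_retention: dict = field(
        default_factory=lambda: {"M18": 0.30, "M36": 0.26, "M54": 0.16}
    )
    class_prevalence: tuple = (0.65, 0.29, 0.045, 0.015)
    progression_drift: float = 0.08
    feature_models: dict = field(default_factory=dict)
    missing_rates: dict = field(default_factory=dict)
    missing_rate_default: float = DEFAULT_MISSING_RATE_OTHER
    diagnosis_agreement: float = DEFAULT_DIAGNOSIS_AGREEMENT
    seed: int = 0

    def __post_init__(self):
        bad = []
        if self.n_subjects <= 0:
            bad.append("n_subjects")
        prev = np.asarray(self.class_prevalence, dtype=float)
        if prev.shape[0] != len(SIM_CDR_CLASSES) or np.any(prev < 0) \
                or abs(prev.sum() - 1.0) > 1e-9:
            bad.append("class_prevalence")
        for v, p in self.visit_retention.items():
            if not 0 <= p <= 1:
                bad.append(f"visit_retention[{v}]")
        if not 0 <= self.progression_drift <= 1:
            bad.append("progression_drift")
        for f, p in {**DEFAULT_MISSING_RATES, **self.missing_rates}.items():
            if not 0 <= p <= 1:
                bad.append(f"missing_rates[{f}]")
        for name, model in self.feature_models.items():
            if "sds" in model and np.any(np.asarray(model["sds"]) <= 0):
                bad.append(f"feature_models[{name}].sds")
        if bad:
            raise ValidationError(f"invalid simulation spec fields: {bad}")


def generate_cohort(spec: CohortSimSpec) -> CohortTable:
    """Draw a complete subject-visit cohort table per ``spec``.

    Reproducible for a fixed seed. CDR is drawn per subject at baseline
    from ``class_prevalence``; at each attended later visit it moves up one
    severity class with probability ``progression_drift``. Features are
    then drawn conditionally on the visit's CDR class, and finally masked
    at the per-feature missing rate.
    """
    dictionary = default_dictionary()
    prev = np.asarray(spec.class_prevalence, dtype=float)
    rng_cdr = np.random.default_rng(substream_seed(spec.seed, "cdr"))
    rng_visits = np.random.default_rng(substream_seed(spec.seed, "visits"))

    rows = []
    for subj in range(spec.n_subjects):
        cls = int(rng_cdr.choice(len(SIM_CDR_CLASSES), p=prev))
        rows.append((f"S{subj:05d}", "BL", cls))
        for visit in ("M18", "M36", "M54"):
            if rng_visits.random() < spec.visit_retention.get(visit, 0.0):
                if rng_cdr.random() < spec.progression_drift:
                    cls = min(cls + 1, len(SIM_CDR_CLASSES) - 1)
                rows.append((f"S{subj:05d}", visit, cls))
    df = pd.DataFrame(rows, columns=["subject_id", "visit", "_cls"])
    n = len(df)
    cls_idx = df.pop("_cls").to_numpy()
    df["cdr"] = np.asarray(SIM_CDR_CLASSES)[cls_idx]

    # clinical diagnosis: noisy relabelling of the merged CDR category
    rng_diag = np.random.default_rng(substream_seed(spec.seed, "diagnosis"))
    merged = np.minimum(cls_idx, 2)            # 0=normal, 1=very mild, 2=mild+
    diag_idx = merged.copy()
    flip = rng_diag.random(n) >= spec.diagnosis_agreement
    step = np.where(merged == 0, 1, np.where(merged == 2, -1,
                    rng_diag.choice([-1, 1], size=n)))
    diag_idx[flip] = merged[flip] + step[flip]
    df["diagnosis"] = np.array(["HC", "MCI", "AD"])[diag_idx]

    cont_models = {**DEFAULT_CONTINUOUS_MODELS,
                   **{k: v for k, v in spec.feature_models.items()
                      if k in DEFAULT_CONTINUOUS_MODELS}}
    for name, model in cont_models.items():
        rng = np.random.default_rng(substream_seed(spec.seed, f"feat|{name}"))
        means = np.asarray(model["means"], float)[cls_idx]
        sds = np.asarray(model["sds"], float)[cls_idx]
        vals = rng.normal(means, sds)
        lo, hi = model.get("clip", (None, None))
        vals = np.clip(vals, lo, hi)
        df[name] = vals

    rng = np.random.default_rng(substream_seed(spec.seed, "feat|apoe"))
    apoe_probs = np.asarray(
        spec.feature_models.get("apoe", DEFAULT_APOE_MODEL), float
    )
    apoe = np.empty(n, dtype=object)
    for c in range(len(SIM_CDR_CLASSES)):
        mask = cls_idx == c
        apoe[mask] = rng.choice(APOE_GENOTYPES, size=int(mask.sum()),
                                p=apoe_probs[c])
    df["apoe"] = apoe

    for name, (mu, sd) in DEFAULT_NOISE_CONTINUOUS.items():
        rng = np.random.default_rng(substream_seed(spec.seed, f"feat|{name}"))
        df[name] = rng.normal(mu, sd, size=n)
    for name, rate in DEFAULT_FLAG_RATES.items():
        rng = np.random.default_rng(substream_seed(spec.seed, f"feat|{name}"))
        df[name] = np.where(rng.random(n) < rate, "yes", "no")
    rng = np.random.default_rng(substream_seed(spec.seed, "feat|sex"))
    df["sex"] = np.where(rng.random(n) < 0.55, "F", "M")

    # missingness masks
    rates = {**DEFAULT_MISSING_RATES, **spec.missing_rates}
    for s in dictionary:
        if s.name == "cdr":
            continue
        rate = rates.get(s.name, spec.missing_rate_default)
        if rate <= 0:
            continue
        rng = np.random.default_rng(substream_seed(spec.seed,
                                                   f"miss|{s.name}"))
        mask = rng.random(n) < rate
        col = df[s.name].astype(object) if s.kind != "continuous" \
            else df[s.name]
        col = col.where(~mask, other=np.nan if s.kind == "continuous"
                        else None)
        df[s.name] = col

    ordered = ["subject_id", "visit", "cdr", "diagnosis"] + [
        s.name for s in dictionary if s.name != "cdr"
    ]
    return CohortTable(df[ordered], dictionary)


# ---------------------------------------------------------------------------
# ground-truth discrete network


def _ordinal_cpt(child_card: int, parent_cards: list[int],
                 parent_values: list[np.ndarray], weights: list[float],
                 base: float, tau: float) -> np.ndarray:
    """Location-family CPT: child states sit on [-1, 1]; parents shift the
    location; ``tau`` sets the spread (small tau = strong dependence)."""
    q = int(np.prod(parent_cards)) if parent_cards else 1
    child_pos = (np.linspace(-1.0, 1.0, child_card) if child_card > 1
                 else np.zeros(1))
    table = np.zeros((q, child_card))
    for j in range(q):
        loc = base
        rem = j
        for card, vals, w in zip(reversed(parent_cards),
                                 reversed(parent_values),
                                 reversed(weights)):
            state = rem % card
            rem //= card
            loc += w * vals[state]
        logits = -((child_pos - loc) ** 2) / (2.0 * tau * tau)
        p = np.exp(logits - logits.max())
        table[j] = p / p.sum()
    return table


def _levels(card: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, card) if card > 1 else np.zeros(1)


def default_ground_truth_network(
    biomarker_weight: float = 0.7,
    biomarker_tau: float = 0.65,
    cognitive_weight: float = 0.9,
    cognitive_tau: float = 0.5,
) -> BayesianNetworkModel:
    """Nine-node generator: age/ApoE -> imaging -> CDR -> cognition.

    Cognitive links (CDR to MMSE/LMDR/LMIR, LMDR to LMIR) default stronger
    than the biomarker links, so learned arc strengths reproduce the
    qualitative ordering of the clinical finding that severity couples most
    tightly to the cognitive assessments.
    """
    categories = {
        "age": ["60-69", "70-79", "80+"],
        "apoe": list(APOE_GENOTYPES),
        "gm_volume": ["low", "mid", "high"],
        "csf_volume": ["low", "mid", "high"],
        "pib_pet_voxels": ["low", "mid", "high"],
        "cdr": ["normal", "very mild", "mild/moderate"],
        "mmse": ["0-9", "10-18", "19-23", "24-30"],
        "lmdr": ["low", "mid", "high"],
        "lmir": ["low", "mid", "high"],
    }
    edges = {
        ("age", "gm_volume"), ("age", "csf_volume"),
        ("age", "pib_pet_voxels"),
        ("apoe", "pib_pet_voxels"),
        ("pib_pet_voxels", "gm_volume"), ("pib_pet_voxels", "csf_volume"),
        ("gm_volume", "csf_volume"),
        ("csf_volume", "cdr"), ("gm_volume", "cdr"),
        ("pib_pet_voxels", "cdr"),
        ("cdr", "mmse"), ("cdr", "lmdr"), ("cdr", "lmir"),
        ("lmdr", "lmir"),
    }
    cards = {v: len(c) for v, c in categories.items()}
    # epsilon-4 allele load of each ApoE genotype, scaled to [-1, 1]
    apoe_load = np.array([-1.0, -1.0, 0.0, 0.0, 1.0])
    parent_vals = {v: _levels(cards[v]) for v in categories}
    parent_vals["apoe"] = apoe_load
    # severity raises PiB and CSF, lowers GM/MMSE/recall; encode with signs
    signed = {
        ("age", "gm_volume"): -1, ("age", "csf_volume"): 1,
        ("age", "pib_pet_voxels"): 1,
        ("apoe", "pib_pet_voxels"): 1,
        ("pib_pet_voxels", "gm_volume"): -1,
        ("pib_pet_voxels", "csf_volume"): 1,
        ("gm_volume", "csf_volume"): -1,
        ("csf_volume", "cdr"): 1, ("gm_volume", "cdr"): -1,
        ("pib_pet_voxels", "cdr"): 1,
        ("cdr", "mmse"): -1, ("cdr", "lmdr"): -1, ("cdr", "lmir"): -1,
        ("lmdr", "lmir"): 1,
    }
    parents_of: dict[str, list] = {v: [] for v in categories}
    for a, b in sorted(edges):
        parents_of[b].append(a)

    cognitive_children = {"mmse", "lmdr", "lmir"}
    root_priors = {
        "age": np.array([0.35, 0.45, 0.20]),
        "apoe": np.array([0.08, 0.55, 0.03, 0.26, 0.08]),
    }
    cpts = {}
    parent_order = {}
    for v in categories:
        parents = sorted(parents_of[v])
        parent_order[v] = parents
        if not parents:
            cpts[v] = root_priors[v][None, :]
            continue
        strong = v in cognitive_children
        w0 = cognitive_weight if strong else biomarker_weight
        tau = cognitive_tau if strong else biomarker_tau
        weights = [w0 * signed[(p, v)] / max(1, len(parents)) ** 0.5
                   for p in parents]
        base = -0.35 if v == "cdr" else 0.0
        cpts[v] = _ordinal_cpt(cards[v], [cards[p] for p in parents],
                               [parent_vals[p] for p in parents],
                               weights, base, tau)
    return BayesianNetworkModel(
        nodes=sorted(categories), categories=categories, edges=edges,
        cpts=cpts, parent_order=parent_order,
    )


#: Numeric stand-ins for the ground-truth network's discrete states, used
#: when re-expressing network samples in the raw cohort schema. The CAIM
#: stage recovers the generating states exactly from these codes.
NETWORK_STATE_VALUES = {
    "age": {"60-69": 65.0, "70-79": 75.0, "80+": 85.0},
    "gm_volume": {"low": 0.0, "mid": 1.0, "high": 2.0},
    "csf_volume": {"low": 0.0, "mid": 1.0, "high": 2.0},
    "pib_pet_voxels": {"low": 0.0, "mid": 1.0, "high": 2.0},
    "lmdr": {"low": 0.0, "mid": 1.0, "high": 2.0},
    "lmir": {"low": 0.0, "mid": 1.0, "high": 2.0},
    "mmse": {"0-9": 5.0, "10-18": 14.0, "19-23": 21.0, "24-30": 27.0},
}
_CDR_STATE_SCORE = {"normal": 0.0, "very mild": 0.5, "mild/moderate": 1.0}
_CDR_STATE_DIAG = {"normal": "HC", "very mild": "MCI",
                   "mild/moderate": "AD"}


def network_cohort(net: BayesianNetworkModel, n: int,
                   seed: int = 0) -> CohortTable:
    """Forward-sample ``net`` and express the draws in the cohort schema.

    Discrete states become numeric codes (ApoE stays categorical), CDR
    states become CDR scores, and the diagnosis column is the deterministic
    image of the CDR category, so the table round-trips the generating
    discretization through the CAIM/fixed schemes.
    """
    sample = sample_from_network(net, n, seed=seed)
    df = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "visit": "BL",
        "cdr": sample["cdr"].map(_CDR_STATE_SCORE).astype(float),
        "diagnosis": sample["cdr"].map(_CDR_STATE_DIAG),
    })
    for name, lut in NETWORK_STATE_VALUES.items():
        if name in sample.columns:
            df[name] = sample[name].map(lut).astype(float)
    if "apoe" in sample.columns:
        df["apoe"] = sample["apoe"]
    return CohortTable(df, default_dictionary())


def sample_from_network(net: BayesianNetworkModel, n: int,
                        seed: int = 0) -> pd.DataFrame:
    """Forward (ancestral) sampling: n i.i.d. joint draws as a DataFrame of
    state labels, columns in node order."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not net.cpts:
        raise GraphError("network has no CPTs")
    order = net.topological_order()
    cards = net.cards()
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for v in order:
        parents = net.parents(v)
        if parents:
            idx = np.zeros(n, dtype=np.int64)
            for p in parents:
                idx = idx * cards[p] + draws[p]
        else:
            idx = np.zeros(n, dtype=np.int64)
        table = np.asarray(net.cpts[v])
        u = rng.random(n)
        cdf = np.cumsum(table, axis=1)
        draws[v] = (u[:, None] > cdf[idx]).sum(axis=1)
    data = {v: np.asarray(net.categories[v], dtype=object)[draws[v]]
            for v in net.nodes}
    return pd.DataFrame(data, columns=list(net.nodes))
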