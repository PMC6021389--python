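"""Supervised discretization.

Continuous features are discretized against the CDR severity classes with
the class-attribute interdependence maximization (CAIM) criterion:

    CAIM = (1/n) * sum_r max_r^2 / M_{+r}

where the sum runs over the n intervals of a candidate scheme, ``max_r`` is
the largest class count within interval r of the class-by-interval quanta
matrix and ``M_{+r}`` is the interval's total count. The greedy algorithm
inserts one boundary at a time, always the candidate midpoint that maximizes
the criterion, and keeps growing while the score strictly improves or while
the scheme still has fewer intervals than there are classes.

Variables with fixed clinical conventions (CDR, MMSE, ApoE genotype) bypass
CAIM and use explicit category maps.

Intervals are left-open/right-closed with infinite outer bounds, so a
learned scheme is total on unseen test values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import (
    DegenerateFeatureError,
    DegenerateIntervalError,
    FeatureLookupError,
    InputError,
    OutOfSupportError,
)

#: CDR severity codes after merging mild and moderate (no severe cases).
CDR_CODES = ("normal", "very mild", "mild/moderate")

#: Clinical MMSE bands (normal / mild / moderate / severe impairment).
#: The convention is configurable; these are the common clinical cut points.
MMSE_BANDS = ((24.0, 30.0), (19.0, 23.0), (10.0, 18.0), (0.0, 9.0))
MMSE_LABELS = ("24-30", "19-23", "10-18", "0-9")

APOE_CODES = ("e3e2", "e3e3", "e4e2", "e4e3", "e4e4")


@dataclass
class QuantaMatrix:
    """Class-by-interval contingency counts underlying the CAIM criterion."""

    counts: np.ndarray          # shape (n_classes, n_intervals)
    class_labels: list
    boundaries: np.ndarray      # strictly increasing interior cut points

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def column_maxima(self) -> np.ndarray:
        return self.counts.max(axis=0)

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[1]


@dataclass
class DiscretizationScheme:
    """Per-feature discretization: CAIM cut points or a fixed category map."""

    feature: str
    mode: str                                  # "caim" | "fixed"
    cut_points: np.ndarray | None = None
    category_map: dict | None = None
    interval_labels: tuple = ()
    achieved_caim: float | None = None

    def __post_init__(self):
        if self.mode not in ("caim", "fixed"):
            raise InputError(f"unknown scheme mode {self.mode!r}")
        if self.mode == "caim":
            self.cut_points = np.asarray(self.cut_points, dtype=float)
            if len(self.interval_labels) != len(self.cut_points) + 1:
                raise InputError(
                    "caim scheme needs len(interval_labels) == len(cut_points)+1"
                )
        elif self.category_map is None:
            raise InputError("fixed scheme needs a category_map")


def build_quanta_matrix(values, classes, boundaries) -> QuantaMatrix:
    """Count observations per (class, interval).

    Interval r is (b_{r-1}, b_r] with implicit outer bounds -inf and +inf.
    Class labels are ordered by first appearance.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    if values.shape[0] != classes.shape[0]:
        raise InputError("values and classes must have equal length")
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size and np.any(np.diff(boundaries) <= 0):
        raise InputError("boundaries must be strictly increasing")
    labels, class_idx = np.unique(classes, return_inverse=True)
    # seen-order labels for stable presentation
    order = np.argsort(np.array([np.argmax(classes == l) for l in labels]))
    labels = labels[order]
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    class_idx = remap[class_idx]
    interval_idx = np.searchsorted(boundaries, values, side="left")
    n_cls, n_int = len(labels), boundaries.size + 1
    counts = np.zeros((n_cls, n_int), dtype=int)
    np.add.at(counts, (class_idx, interval_idx), 1)
    return QuantaMatrix(counts, list(labels), boundaries)


def caim_score(q: QuantaMatrix) -> float:
    """CAIM criterion of a quanta matrix: (1/n) sum_r max_r^2 / M_{+r}."""
    totals = q.column_totals
    if np.any(totals == 0):
        raise DegenerateIntervalError(
            f"empty interval(s) at columns {np.flatnonzero(totals == 0).tolist()}"
        )
    return float(np.sum(q.column_maxima.astype(float) ** 2 / totals)
                 / q.n_intervals)


def _caim_from_cumulative(cum: np.ndarray, cut_idx: np.ndarray) -> float:
    """CAIM from per-class cumulative counts at candidate positions.

    ``cum[c, j]`` = count of class c among the first j sorted observations;
    ``cut_idx`` = observation counts at each interior boundary (increasing).
    """
    edges = np.concatenate(([0], cut_idx, [cum.shape[1] - 1]))
    seg = cum[:, edges[1:]] - cum[:, edges[:-1]]      # class counts per interval
    totals = seg.sum(axis=0)
    if np.any(totals == 0):
        return -np.inf
    return float(np.sum(seg.max(axis=0).astype(float) ** 2 / totals)
                 / (len(edges) - 1))


def caim_discretize(values, classes,
                    max_intervals: int | None = None,
                    feature: str = "") -> DiscretizationScheme:
    """Greedy CAIM discretization of one continuous feature.

    Candidate boundaries are midpoints between consecutive distinct sorted
    values. Growth continues while the criterion strictly improves, or while
    the interval count is still below the number of classes; ties in the
    greedy argmax break toward the smaller cut point.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    if values.shape[0] != classes.shape[0]:
        raise InputError("values and classes must have equal length")
    keep = ~np.isnan(values)
    values, classes = values[keep], classes[keep]
    distinct = np.unique(values)
    if distinct.size < 2:
        raise DegenerateFeatureError("all values identical")
    class_labels = np.unique(classes)
    if class_labels.size < 2:
        raise DegenerateFeatureError("only one class present")

    order = np.argsort(values, kind="stable")
    sv = values[order]
    sc = classes[order]
    # cumulative class counts over the sorted sample
    onehot = (sc[None, :] == class_labels[:, None]).astype(int)
    cum = np.concatenate(
        [np.zeros((class_labels.size, 1), int), np.cumsum(onehot, axis=1)],
        axis=1,
    )
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    # number of sorted observations <= each candidate cut
    cand_idx = np.searchsorted(sv, midpoints, side="right")

    n_classes = class_labels.size
    chosen: list[int] = []          # indices into midpoints, kept sorted
    best_score = _caim_from_cumulative(cum, np.array([], dtype=int))
    while True:
        if max_intervals is not None and len(chosen) + 1 >= max_intervals:
            break
        remaining = [i for i in range(midpoints.size) if i not in chosen]
        if not remaining:
            break
        cand_score = -np.inf
        cand = None
        for i in remaining:
            cuts = np.sort(cand_idx[np.array(chosen + [i])])
            s = _caim_from_cumulative(cum, cuts)
            if s > cand_score:      # strict: ties keep the smaller cut point
                cand_score, cand = s, i
        if cand is None or cand_score == -np.inf:
            break
        if cand_score > best_score or len(chosen) + 1 < n_classes:
            chosen.append(cand)
            chosen.sort()
            best_score = cand_score
        else:
            break

    cuts = midpoints[np.array(chosen, dtype=int)] if chosen else np.array([])
    labels = tuple(range(len(cuts) + 1))
    return DiscretizationScheme(
        feature=feature, mode="caim", cut_points=np.sort(cuts),
        interval_labels=labels, achieved_caim=best_score,
    )


def fixed_scheme(feature: str) -> DiscretizationScheme:
    """Fixed clinical category maps for CDR, MMSE and the ApoE genotype.

    CDR merges mild and moderate into one category (no severe cases are in
    scope; encountering CDR=3 raises). MMSE uses the four clinical bands;
    ApoE keeps its five allele combinations.
    """
    if feature == "cdr":
        return DiscretizationScheme(
            feature="cdr", mode="fixed",
            category_map={0.0: "normal", 0.5: "very mild",
                          1.0: "mild/moderate", 2.0: "mild/moderate"},
            interval_labels=CDR_CODES,
        )
    if feature == "mmse":
        # interval-based convention, reuse the caim cut-point machinery
        return DiscretizationScheme(
            feature="mmse", mode="caim",
            cut_points=np.array([9.5, 18.5, 23.5]),
            interval_labels=("0-9", "10-18", "19-23", "24-30"),
        )
    if feature == "apoe":
        return DiscretizationScheme(
            feature="apoe", mode="fixed",
            category_map={g: g for g in APOE_CODES},
            interval_labels=APOE_CODES,
        )
    raise FeatureLookupError(feature)


def apply_scheme(values, scheme: DiscretizationScheme) -> np.ndarray:
    """Map raw values to interval codes; missing stays missing.

    Values equal to a cut point land in the lower interval (right-closed).
    """
    values = np.asarray(values, dtype=object)
    out = np.empty(values.shape[0], dtype=object)
    if scheme.mode == "caim":
        numeric = np.array(
            [np.nan if _missing(v) else float(v) for v in values]
        )
        idx = np.searchsorted(scheme.cut_points, numeric, side="left")
        for i, v in enumerate(numeric):
            out[i] = None if np.isnan(v) else scheme.interval_labels[idx[i]]
    else:
        for i, v in enumerate(values):
            if _missing(v):
                out[i] = None
                continue
            key = float(v) if scheme.feature == "cdr" else v
            if scheme.feature == "cdr" and key == 3.0:
                raise OutOfSupportError(
                    "CDR=3 (severe) is outside the supported categories"
                )
            if key not in scheme.category_map:
                raise OutOfSupportError(
                    f"{scheme.feature}: value {v!r} outside category map"
                )
            out[i] = scheme.category_map[key]
    return out


def _missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False


def learn_schemes(df, dictionary, target: str = "cdr",
                  max_intervals: int = 3) -> dict[str, DiscretizationScheme]:
    """Learn one scheme per feature on a development table.

    CDR, MMSE and ApoE use their fixed clinical conventions; every other
    continuous feature is CAIM-discretized against the merged CDR codes
    with at most ``max_intervals`` (= number of CDR classes) intervals.
    Categorical features keep their categories as codes (identity map).
    """
    cdr_codes = apply_scheme(df[target].to_numpy(), fixed_scheme("cdr"))
    schemes: dict[str, DiscretizationScheme] = {}
    for spec in dictionary:
        name = spec.name
        if name not in df.columns:
            continue
        if name in ("cdr", "mmse", "apoe"):
            schemes[name] = fixed_scheme(name)
        elif spec.kind == "continuous":
            vals = df[name].to_numpy(dtype=float)
            mask = ~np.isnan(vals) & np.array([c is not None
                                               for c in cdr_codes])
            schemes[name] = caim_discretize(
                vals[mask], cdr_codes[mask],
                max_intervals=max_intervals, feature=name,
            )
        else:
            schemes[name] = DiscretizationScheme(
                feature=name, mode="fixed",
                category_map={c: c for c in spec.categories},
                interval_labels=tuple(spec.categories),
            )
    return schemes


def apply_schemes(df, schemes: dict[str, DiscretizationScheme]):
    """Apply learned schemes column-wise; returns a new DataFrame of codes."""
    out = df.copy()
    for name, scheme in schemes.items():
        if name in out.columns:
            out[name] = apply_scheme(out[name].to_numpy(), scheme)
    return out


def save_schemes(schemes: dict[str, DiscretizationScheme], path) -> None:
    doc = {}
    for name, s in schemes.items():
        entry: dict = {"mode": s.mode,
                       "interval_labels": list(s.interval_labels)}
        if s.cut_points is not None:
            entry["cut_points"] = [float(c) for c in s.cut_points]
        if s.category_map is not None:
            entry["category_map"] = {str(k): v for k, v in s.category_map.items()}
        if s.achieved_caim is not None:
            entry["achieved_caim"] = float(s.achieved_caim)
        doc[name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_schemes(path) -> dict[str, DiscretizationScheme]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    schemes = {}
    for name, e in doc.items():
        cmap = e.get("category_map")
        if cmap is not None and name == "cdr":
            cmap = {float(k): v for k, v in cmap.items()}
        schemes[name] = DiscretizationScheme(
            feature=name, mode=e["mode"],
            cut_points=np.asarray(e["cut_points"], float)
            if "cut_points" in e else None,
            category_map=cmap,
            interval_labels=tuple(e["interval_labels"]),
            achieved_caim=e.get("achieved_caim"),
        )
    return schemes
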