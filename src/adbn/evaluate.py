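"""Performance measurement: splits, multi-class accuracy with exact CI,
macro one-vs-rest AUC, per-class sensitivity/specificity, correlation
validation and experiment runners for feature-subset and network
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InputError,
    StratificationError,
    UndefinedCorrelationError,
)


# ---------------------------------------------------------------------------
# splits


def holdout_split(df: pd.DataFrame, fraction: float,
                  stratify_by: str | None = None,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (development, test); ``fraction`` goes to the test side.

    Stratified when ``stratify_by`` is given: each stratum contributes
    round(fraction * n_s) test rows, at least 1 and at most n_s - 1.
    Deterministic given ``seed``; the two sides are disjoint and exhaustive.
    """
    if not 0 < fraction < 1:
        raise InputError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(df)
    if stratify_by is None:
        idx = rng.permutation(n)
        n_test = int(round(fraction * n))
        test_pos = np.sort(idx[:n_test])
    else:
        groups = df.groupby(stratify_by, sort=True, dropna=False).indices
        test_parts = []
        for key in sorted(groups, key=str):
            pos = np.asarray(groups[key])
            if len(pos) < 2:
                raise StratificationError(
                    f"stratum {key!r} has {len(pos)} record(s); "
                    "cannot appear on both sides"
                )
            k = int(round(fraction * len(pos)))
            k = max(1, min(k, len(pos) - 1))
            perm = rng.permutation(len(pos))
            test_parts.append(pos[perm[:k]])
        test_pos = np.sort(np.concatenate(test_parts))
    mask = np.zeros(n, dtype=bool)
    mask[test_pos] = True
    return df.iloc[~mask].copy(), df.iloc[mask].copy()


def kfold_indices(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Random fold assignment: array of length n with values in 0..k-1.

    Fold sizes differ by at most one record.
    """
    if k > n:
        raise InputError(f"k={k} exceeds n={n}")
    if k < 1:
        raise InputError("k must be positive")
    rng = np.random.default_rng(seed)
    assignment = np.tile(np.arange(k), n // k + 1)[:n]
    return assignment[rng.permutation(n)]


# ---------------------------------------------------------------------------
# metrics


def multiclass_accuracy(truth, predicted) -> dict:
    """Proportion correct with an exact (Clopper–Pearson) 95% CI."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape[0] != predicted.shape[0]:
        raise InputError("truth and predicted must have equal length")
    n = truth.shape[0]
    if n == 0:
        raise InputError("empty input")
    x = int(np.sum(truth == predicted))
    point = x / n
    lo = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))
    return {"mca": point, "ci95": (lo, hi), "n": n, "correct": x}


def _binary_auc(pos_mask: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney AUC with midrank tie handling."""
    ranks = stats.rankdata(score)
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    u = ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def multiclass_auc(truth, posterior: np.ndarray,
                   class_labels: list, average: str = "macro") -> float:
    """Macro average of one-vs-rest AUCs from posterior probabilities.

    ``posterior[i, c]`` is the probability of class ``class_labels[c]`` for
    record i; rows must sum to 1. Classes absent from ``truth`` are
    excluded with a warning. ``average="pairwise"`` gives the Hand–Till
    style mean over ordered class pairs instead.
    """
    truth = np.asarray(truth)
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape != (truth.shape[0], len(class_labels)):
        raise InputError("posterior shape must be (n_records, n_classes)")
    if not np.allclose(posterior.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("posterior rows must sum to 1")
    present = [c for c in class_labels if np.any(truth == c)]
    if not present:
        raise InputError("no class of class_labels appears in truth")
    if len(present) < len(class_labels):
        warnings.warn(
            f"classes absent from truth excluded from AUC: "
            f"{sorted(set(map(str, class_labels)) - set(map(str, present)))}"
        )
    if average == "macro":
        aucs = []
        for c in present:
            pos = truth == c
            if pos.all():
                continue
            aucs.append(_binary_auc(pos, posterior[:, class_labels.index(c)]))
        if not aucs:
            raise InputError("need both positives and negatives for AUC")
        return float(np.mean(aucs))
    if average == "pairwise":
        aucs = []
        for a in present:
            for b in present:
                if a == b:
                    continue
                mask = (truth == a) | (truth == b)
                pos = truth[mask] == a
                aucs.append(_binary_auc(
                    pos, posterior[mask, class_labels.index(a)]
                ))
        return float(np.mean(aucs))
    raise InputError(f"unknown average {average!r}")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray     # rows = truth, columns = prediction
    class_labels: list

    @classmethod
    def from_labels(cls, truth, predicted, class_labels) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        k = len(class_labels)
        idx = {c: i for i, c in enumerate(class_labels)}
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(truth, predicted):
            counts[idx[t], idx[p]] += 1
        return cls(counts, list(class_labels))


def sensitivity_specificity(confusion: ConfusionMatrix) -> dict:
    """One-vs-rest per-class sensitivity and specificity.

    Undefined denominators (a class without truth rows, or a class covering
    every row) are reported as None rather than 0.
    """
    m = confusion.counts
    total = m.sum()
    out = {}
    for i, c in enumerate(confusion.class_labels):
        tp = m[i, i]
        fn = m[i].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        out[c] = {"sensitivity": sens, "specificity": spec}
    return out


def pearson_correlation(x, y) -> dict:
    """Pearson r with Fisher-z 95% CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise InputError("x and y must have equal length")
    if x.shape[0] < 3:
        raise InputError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = x.shape[0]
    if abs(r) >= 1.0:
        ci = (float(r), float(r))
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        q = stats.norm.ppf(0.975)
        ci = (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))
    return {"r": float(r), "ci95": ci, "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# reports and experiment runners


@dataclass
class EvaluationReport:
    mca: float
    mca_ci95: tuple
    auc: float
    per_class: dict
    n_test: int
    split: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "mca": self.mca,
            "mca_ci95": list(self.mca_ci95),
            "auc": self.auc,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "n_test": self.n_test,
            "split": self.split,
            "seed": self.seed,
        }


def argmax_severe(posterior: np.ndarray, class_labels: list) -> list:
    """Hard predictions: posterior argmax, ties toward the more severe
    (later-listed) class."""
    out = []
    for row in posterior:
        best = row.max()
        winners = [i for i, p in enumerate(row) if p == best]
        out.append(class_labels[winners[-1]])
    return out


def evaluate_predictions(truth, posterior, class_labels,
                         split: str = "", seed=None) -> EvaluationReport:
    pred = argmax_severe(np.asarray(posterior), class_labels)
    acc = multiclass_accuracy(truth, pred)
    auc = multiclass_auc(truth, posterior, class_labels)
    cm = ConfusionMatrix.from_labels(truth, pred, class_labels)
    return EvaluationReport(
        mca=acc["mca"], mca_ci95=acc["ci95"], auc=auc,
        per_class=sensitivity_specificity(cm),
        n_test=len(truth), split=split, seed=seed,
    )


def evaluate_feature_subsets(data: pd.DataFrame, subsets: list,
                             target: str, constraints=None,
                             score: str = "bic", seed: int = 0,
                             test_fraction: float = 0.1,
                             ess: float = 10.0,
                             smoothing: float = 1.0) -> dict:
    """Learn/fit/predict/evaluate on the identical split per feature subset.

    ``data`` must already be discrete. Returns {subset key: EvaluationReport}
    with the subset key a '+'-joined sorted feature string.
    """
    from .bayesnet import (StructureConstraints, fit_cpts, hill_climb,
                           infer_categories, posterior_table)

    for sub in subsets:
        if not sub:
            raise InputError("empty feature subset")
        missing = [f for f in sub if f not in data.columns]
        if missing:
            raise InputError(f"subset features not in data: {missing}")
    dev, test = holdout_split(data, test_fraction, stratify_by=target,
                              seed=seed)
    reports = {}
    for sub in subsets:
        cols = sorted(sub) + [target]
        sub_constraints = _restrict_constraints(constraints, set(cols))
        categories = infer_categories(data[cols])
        structure = hill_climb(dev[cols], sub_constraints, score=score,
                               ess=ess, categories=categories)
        model = fit_cpts(structure, dev[cols], smoothing=smoothing,
                         categories=categories)
        post = posterior_table(model, test, target,
                               evidence_nodes=sorted(sub))
        reports["+".join(sorted(sub))] = evaluate_predictions(
            test[target].to_numpy(), post, model.categories[target],
            split=f"holdout {test_fraction}", seed=seed,
        )
    return reports


def _restrict_constraints(constraints, nodes: set):
    from .bayesnet import StructureConstraints

    if constraints is None:
        return None
    return StructureConstraints(
        required_edges={e for e in constraints.required_edges
                        if e[0] in nodes and e[1] in nodes},
        forbidden_edges={e for e in constraints.forbidden_edges
                         if e[0] in nodes and e[1] in nodes},
        tier_order=[[v for v in block if v in nodes]
                    for block in constraints.tier_order],
    )


def compare_networks(model_a, model_b) -> dict:
    """Structural diff keyed by edge: added, removed, reversed."""
    ea, eb = set(model_a.edges), set(model_b.edges)
    reversed_edges = sorted((a, b) for a, b in ea
                            if (b, a) in eb and (a, b) not in eb)
    removed = sorted(e for e in ea - eb
                     if (e[1], e[0]) not in eb)
    added = sorted(e for e in eb - ea
                   if (e[1], e[0]) not in ea)
    node_diff = sorted(set(model_a.nodes) ^ set(model_b.nodes), key=str)
    return {
        "added": added,
        "removed": removed,
        "reversed": reversed_edges,
        "node_symmetric_difference": node_diff,
    }
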