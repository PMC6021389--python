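"""SMOTE class balancing on mixed discretized features.

Synthetic minority instances are interpolated between a minority record and
one of its k nearest minority neighbours. The distance on mixed data is
Euclidean over ordinal interval codes (treated as integers) plus a
per-mismatch penalty of 1 for nominal codes (SMOTE-NC style). Ordinal
synthetic coordinates are rounded back to the nearest valid code; nominal
coordinates take the majority value among the k neighbours (ties keep the
seed record's value). Synthetic rows are flagged so balancing is reversible.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientNeighborsError

SYNTHETIC_FLAG = "is_synthetic"


def _column_kinds(df: pd.DataFrame, features: list[str]) -> dict[str, str]:
    kinds = {}
    for f in features:
        col = df[f]
        if pd.api.types.is_numeric_dtype(col):
            kinds[f] = "numeric"
        else:
            kinds[f] = "nominal"
    return kinds


def _distance_matrix(num: np.ndarray, nom: np.ndarray) -> np.ndarray:
    d2 = np.zeros((num.shape[0], num.shape[0]))
    if num.shape[1]:
        diff = num[:, None, :] - num[None, :, :]
        d2 += np.sum(diff * diff, axis=2)
    if nom.shape[1]:
        mism = (nom[:, None, :] != nom[None, :, :]).sum(axis=2)
        d2 += mism.astype(float)
    return np.sqrt(d2)


def smote_oversample(rows: pd.DataFrame, features: list[str],
                     amount: float, k_neighbors: int,
                     seed: int) -> pd.DataFrame:
    """Generate ceil(amount/100 * n) synthetic rows from minority ``rows``.

    Continuous/ordinal coordinates are convex combinations x + u (z - x)
    with u ~ U[0, 1]; nominal coordinates by neighbour majority vote.
    """
    n = len(rows)
    if amount < 0:
        raise InputError("amount must be non-negative")
    if k_neighbors < 1:
        raise InputError("k_neighbors must be >= 1")
    n_syn = math.ceil(amount / 100.0 * n)
    if n_syn == 0:
        return rows.iloc[0:0].copy()
    if n < 2:
        raise InsufficientNeighborsError(
            "need at least 2 minority records for SMOTE"
        )
    k = min(k_neighbors, n - 1)

    kinds = _column_kinds(rows, features)
    num_cols = [f for f in features if kinds[f] == "numeric"]
    nom_cols = [f for f in features if kinds[f] == "nominal"]
    num = rows[num_cols].to_numpy(dtype=float) if num_cols else \
        np.zeros((n, 0))
    nom = rows[nom_cols].to_numpy(dtype=object) if nom_cols else \
        np.zeros((n, 0), dtype=object)

    dist = _distance_matrix(num, nom)
    np.fill_diagonal(dist, np.inf)
    # stable k-NN: sort by (distance, index)
    neigh = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    out_rows = []
    for j in range(n_syn):
        i = int(rng.integers(n))
        z = int(neigh[i, int(rng.integers(k))])
        u = float(rng.random())
        rec = rows.iloc[i].copy()
        for ci, f in enumerate(num_cols):
            lo = num[i, ci]
            rec[f] = lo + u * (num[z, ci] - lo)
        for ci, f in enumerate(nom_cols):
            vals = list(nom[neigh[i], ci])
            counts: dict = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            winners = [v for v, c in counts.items() if c == best]
            rec[f] = nom[i, ci] if len(winners) > 1 else winners[0]
        out_rows.append(rec)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    out[SYNTHETIC_FLAG] = 1
    return out


def round_ordinal(values: np.ndarray, valid_codes) -> np.ndarray:
    """Snap interpolated ordinal values to the nearest valid code."""
    codes = np.asarray(sorted(valid_codes), dtype=float)
    values = np.asarray(values, dtype=float)
    idx = np.abs(values[:, None] - codes[None, :]).argmin(axis=1)
    return codes[idx]


def balance_classes(df: pd.DataFrame, features: list[str], target: str,
                    k_neighbors: int = 5, seed: int = 0,
                    ordinal_codes: dict | None = None,
                    skip_singletons: bool = False) -> pd.DataFrame:
    """Oversample every class up to the majority count.

    Original rows are preserved verbatim (flag 0); synthetic rows are
    appended with flag 1. ``ordinal_codes`` optionally maps numeric feature
    names to their valid code sets for post-interpolation rounding.
    A class with a single record cannot be interpolated; by default this
    raises, with ``skip_singletons`` it is left at its observed count.
    """
    counts = df[target].value_counts()
    if len(counts) < 2:
        raise InputError("need at least 2 classes to balance")
    majority = int(counts.max())
    out = df.copy()
    out[SYNTHETIC_FLAG] = 0
    synthetic = []
    for cls in sorted(counts.index, key=str):
        n_cls = int(counts[cls])
        deficit = majority - n_cls
        if deficit == 0:
            continue
        if n_cls < 2:
            if skip_singletons:
                continue
            raise InsufficientNeighborsError(
                f"class {cls!r} has a single record; cannot oversample"
            )
        rows = df[df[target] == cls]
        amount = 100.0 * deficit / n_cls
        syn = smote_oversample(rows, features, amount, k_neighbors,
                               seed=_class_seed(seed, cls))
        syn = syn.iloc[:deficit]
        if ordinal_codes:
            for f, codes in ordinal_codes.items():
                if f in syn.columns:
                    syn[f] = round_ordinal(syn[f].to_numpy(), codes)
        synthetic.append(syn)
    if synthetic:
        out = pd.concat([out] + synthetic, ignore_index=True)
    return out


def _class_seed(seed: int, cls) -> int:
    import hashlib

    h = hashlib.sha256(f"{seed}|{cls}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
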