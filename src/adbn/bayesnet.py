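"""Discrete Bayesian networks: constrained score-based structure learning,
CPT estimation, exact inference and arc strength.

A network over discrete variables X = {X1..Xn} factorizes the joint as
P(X) = prod_i P(Xi | pa(Xi)). Structures are learned by hill climbing over
single-edge additions, deletions and reversals under domain constraints
(required edges, forbidden edges, and tier ordering: edges may only point
from an earlier-or-same tier to a later tier). Four decomposable scores are
available, all in natural-log space:

* ``k2``   — Cooper–Herskovitz marginal likelihood, Dirichlet(1,...,1) rows
* ``bde``  — Bayesian Dirichlet equivalent, equivalent sample size ``ess``
             spread uniformly over the family's joint configurations
* ``mbde`` — BDe variant whose per-parent-row prior mass is proportional to
             the observed parent-configuration frequency: the row prior is
             ess * N_j / N, split evenly over the child's states
* ``bic``  — maximized log likelihood minus (d/2) log N with
             d = (r - 1) * q free parameters per family

Fit quality is compared by k-fold cross-validated log-likelihood loss
(negative mean per-record log joint probability). Posteriors for
classification come from exact variable elimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ConstraintError, GraphError, InputError

SCORES = ("k2", "bde", "mbde", "bic")


# ---------------------------------------------------------------------------
# model containers


@dataclass
class StructureConstraints:
    """Prior-knowledge constraints for structure search."""

    required_edges: set = field(default_factory=set)
    forbidden_edges: set = field(default_factory=set)
    tier_order: list = field(default_factory=list)  # list of variable blocks

    def __post_init__(self):
        self.required_edges = {tuple(e) for e in self.required_edges}
        self.forbidden_edges = {tuple(e) for e in self.forbidden_edges}
        clash = self.required_edges & self.forbidden_edges
        if clash:
            raise ConstraintError(f"edges both required and forbidden: {clash}")
        self._tier = {}
        for i, block in enumerate(self.tier_order):
            for v in block:
                self._tier[v] = i
        for a, b in self.required_edges:
            if not self.allows(a, b):
                raise ConstraintError(f"required edge {a}->{b} violates tiers")
        g = nx.DiGraph(self.required_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ConstraintError("required edges contain a cycle")

    def allows(self, a: str, b: str) -> bool:
        """True when edge a->b is legal under forbidden list and tiers."""
        if (a, b) in self.forbidden_edges:
            return False
        ta, tb = self._tier.get(a), self._tier.get(b)
        if ta is not None and tb is not None and ta > tb:
            return False
        return True


@dataclass
class BayesianNetworkModel:
    """DAG + per-node CPTs + learned-score metadata.

    ``cpts[node]`` has shape (q, r): one normalized row per parent
    configuration (row-major in the stored parent order), r child states.
    """

    nodes: list
    categories: dict                 # node -> list of state labels
    edges: set = field(default_factory=set)
    cpts: dict = field(default_factory=dict)
    parent_order: dict = field(default_factory=dict)
    score_used: str | None = None
    score_value: float | None = None

    def __post_init__(self):
        self.edges = {tuple(e) for e in self.edges}
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("edge set contains a cycle")
        for node, table in self.cpts.items():
            rows = np.asarray(table)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise GraphError(f"CPT rows of {node} do not sum to 1")

    def parents(self, node) -> list:
        if node in self.parent_order:
            return list(self.parent_order[node])
        return sorted(a for a, b in self.edges if b == node)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list:
        return list(nx.lexicographical_topological_sort(self.graph(),
                                                        key=str))

    def cards(self) -> dict:
        return {v: len(self.categories[v]) for v in self.nodes}

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": list(self.nodes),
            "categories": {v: list(map(_jsonable, self.categories[v]))
                           for v in self.nodes},
            "edges": sorted(map(list, self.edges)),
            "parent_order": {v: list(p) for v, p in self.parent_order.items()},
            "cpts": {v: np.asarray(t).tolist() for v, t in self.cpts.items()},
            "score_used": self.score_used,
            "score_value": self.score_value,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BayesianNetworkModel":
        doc = json.loads(text)
        return cls(
            nodes=doc["nodes"],
            categories={v: c for v, c in doc["categories"].items()},
            edges={tuple(e) for e in doc["edges"]},
            cpts={v: np.asarray(t, float) for v, t in doc["cpts"].items()},
            parent_order={v: list(p) for v, p in doc["parent_order"].items()},
            score_used=doc.get("score_used"),
            score_value=doc.get("score_value"),
        )

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for a, b in sorted(self.edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# data encoding


def encode_data(data: pd.DataFrame, categories: dict) -> dict[str, np.ndarray]:
    """Map each column to integer state indices per the category lists."""
    enc = {}
    for v, cats in categories.items():
        lut = {c: i for i, c in enumerate(cats)}
        col = data[v]
        try:
            enc[v] = col.map(lut).to_numpy(dtype=float)
        except TypeError:
            enc[v] = np.array([lut.get(x, np.nan) for x in col], dtype=float)
        if np.isnan(enc[v]).any():
            bad = sorted({str(x) for x in col[pd.isna(col.map(lut))]})
            raise InputError(f"{v}: values outside category list: {bad}")
        enc[v] = enc[v].astype(np.int64)
    return enc


def infer_categories(data: pd.DataFrame, nodes=None) -> dict:
    nodes = list(data.columns) if nodes is None else list(nodes)
    return {v: sorted(data[v].dropna().unique().tolist(), key=str)
            for v in nodes}


# ---------------------------------------------------------------------------
# family scores


def _family_counts(enc: dict, node: str, parents: list, cards: dict):
    """N_jk counts: shape (q, r) over parent configs x child states."""
    r = cards[node]
    q = 1
    for p in parents:
        q *= cards[p]
    child = enc[node]
    if parents:
        idx = np.zeros(child.shape[0], dtype=np.int64)
        for p in parents:
            idx = idx * cards[p] + enc[p]
    else:
        idx = np.zeros(child.shape[0], dtype=np.int64)
    flat = idx * r + child
    counts = np.bincount(flat, minlength=q * r).reshape(q, r)
    return counts


def family_score(enc: dict, node: str, parents: list, cards: dict,
                 score: str, ess: float = 10.0,
                 n_records: int | None = None) -> float:
    """Decomposable log family score of ``node`` given ``parents``."""
    if score not in SCORES:
        raise InputError(f"unknown score {score!r}")
    if score in ("bde", "mbde") and ess <= 0:
        raise InputError("ess must be positive for bde/mbde")
    if node in parents:
        raise InputError("node cannot be its own parent")
    counts = _family_counts(enc, node, list(parents), cards)
    q, r = counts.shape
    nj = counts.sum(axis=1)
    n = int(nj.sum()) if n_records is None else n_records

    if score == "k2":
        # Dirichlet(1..1) rows: log prod_j (r-1)!/(N_j+r-1)! prod_k N_jk!
        val = (gammaln(r) - gammaln(nj + r) + gammaln(counts + 1).sum(axis=1))
        return float(val.sum())
    if score == "bde":
        a_jk = ess / (q * r)
        a_j = ess / q
        val = (gammaln(a_j) - gammaln(a_j + nj)
               + gammaln(counts + a_jk).sum(axis=1) - r * gammaln(a_jk))
        return float(val.sum())
    if score == "mbde":
        # data-adaptive row prior: mass ess*N_j/N per observed parent row,
        # uniform over child states; empty rows contribute nothing
        seen = nj > 0
        a_j = ess * nj[seen] / n
        a_jk = (a_j / r)[:, None]
        val = (gammaln(a_j) - gammaln(a_j + nj[seen])
               + (gammaln(counts[seen] + a_jk) - gammaln(a_jk)).sum(axis=1))
        return float(val.sum())
    # bic
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log(counts) - np.log(nj[:, None]))
    ll = float(np.nansum(ll[counts > 0]))
    d = (r - 1) * q
    return ll - 0.5 * d * np.log(n)


def network_score(edges, data: pd.DataFrame, score: str,
                  ess: float = 10.0, categories: dict | None = None) -> float:
    """Sum of family scores over all nodes (decomposability)."""
    categories = categories or infer_categories(data)
    g = nx.DiGraph()
    g.add_nodes_from(categories)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise GraphError("cycle in proposed structure")
    enc = encode_data(data, categories)
    cards = {v: len(c) for v, c in categories.items()}
    n = len(data)
    return sum(
        family_score(enc, v, sorted(g.predecessors(v)), cards, score, ess, n)
        for v in categories
    )


# ---------------------------------------------------------------------------
# hill climbing


def hill_climb(data: pd.DataFrame,
               constraints: StructureConstraints | None = None,
               score: str = "bic", ess: float = 10.0,
               max_iter: int = 200, seed: int = 0,
               categories: dict | None = None) -> BayesianNetworkModel:
    """Greedy structure search over add/delete/reverse moves.

    Starts from the required-edges graph; at each step applies the legal
    move with the largest strictly positive score gain (deterministic
    tie-break on the lexicographically smallest move). Required edges are
    never deleted or reversed; forbidden edges and tier violations are never
    introduced; acyclicity is maintained. The score trajectory is
    non-decreasing.
    """
    constraints = constraints or StructureConstraints()
    categories = categories or infer_categories(data)
    nodes = sorted(categories, key=str)
    cards = {v: len(c) for v, c in categories.items()}
    enc = encode_data(data, categories)
    n = len(data)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.required_edges)

    def fam(node, parents):
        return family_score(enc, node, sorted(parents), cards, score, ess, n)

    fam_cache = {v: fam(v, list(g.predecessors(v))) for v in nodes}

    def would_cycle(a, b):
        # adding a->b creates a cycle iff b already reaches a
        return nx.has_path(g, b, a)

    for _ in range(max_iter):
        best_gain = 0.0
        best_move = None
        edges = set(g.edges())
        for a, b in ((a, b) for a in nodes for b in nodes if a != b):
            if (a, b) in edges:
                # deletion
                if (a, b) not in constraints.required_edges:
                    gain = fam(b, set(g.predecessors(b)) - {a}) - fam_cache[b]
                    if gain > best_gain:
                        best_gain, best_move = gain, ("del", a, b)
                # reversal
                if ((a, b) not in constraints.required_edges
                        and constraints.allows(b, a)
                        and (b, a) not in edges):
                    g.remove_edge(a, b)
                    cyc = nx.has_path(g, a, b)
                    g.add_edge(a, b)
                    if not cyc:
                        gain = (
                            fam(b, set(g.predecessors(b)) - {a})
                            + fam(a, set(g.predecessors(a)) | {b})
                            - fam_cache[b] - fam_cache[a]
                        )
                        move = ("rev", a, b)
                        if gain > best_gain:
                            best_gain, best_move = gain, move
            else:
                # addition
                if constraints.allows(a, b) and not would_cycle(a, b):
                    gain = fam(b, set(g.predecessors(b)) | {a}) - fam_cache[b]
                    move = ("add", a, b)
                    if gain > best_gain:
                        best_gain, best_move = gain, move
        if best_move is None:
            break
        kind, a, b = best_move
        if kind == "add":
            g.add_edge(a, b)
            fam_cache[b] = fam(b, list(g.predecessors(b)))
        elif kind == "del":
            g.remove_edge(a, b)
            fam_cache[b] = fam(b, list(g.predecessors(b)))
        else:
            g.remove_edge(a, b)
            g.add_edge(b, a)
            fam_cache[a] = fam(a, list(g.predecessors(a)))
            fam_cache[b] = fam(b, list(g.predecessors(b)))

    model = BayesianNetworkModel(
        nodes=nodes, categories=categories, edges=set(g.edges()),
        score_used=score, score_value=float(sum(fam_cache.values())),
    )
    return model


# ---------------------------------------------------------------------------
# parameters, likelihood, CV score selection


def fit_cpts(model_or_edges, data: pd.DataFrame, smoothing: float = 1.0,
             categories: dict | None = None) -> BayesianNetworkModel:
    """Maximum-likelihood / Laplace-smoothed CPTs for a fixed structure.

    Rows are (count + smoothing) normalized per parent configuration;
    parent configurations never seen in ``data`` get the uniform row.
    """
    if isinstance(model_or_edges, BayesianNetworkModel):
        categories = categories or model_or_edges.categories
        edges = model_or_edges.edges
        score_used = model_or_edges.score_used
        score_value = model_or_edges.score_value
    else:
        categories = categories or infer_categories(data)
        edges = {tuple(e) for e in model_or_edges}
        score_used = score_value = None
    g = nx.DiGraph()
    g.add_nodes_from(categories)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise GraphError("cycle in structure")
    cards = {v: len(c) for v, c in categories.items()}
    enc = encode_data(data, categories)
    cpts = {}
    parent_order = {}
    for v in categories:
        parents = sorted(g.predecessors(v))
        parent_order[v] = parents
        counts = _family_counts(enc, v, parents, cards).astype(float)
        counts += smoothing
        rowsum = counts.sum(axis=1, keepdims=True)
        table = np.where(rowsum > 0, counts / np.where(rowsum == 0, 1, rowsum),
                         1.0 / cards[v])
        empty = rowsum[:, 0] == 0
        table[empty] = 1.0 / cards[v]
        cpts[v] = table
    return BayesianNetworkModel(
        nodes=sorted(categories, key=str), categories=categories,
        edges=edges, cpts=cpts, parent_order=parent_order,
        score_used=score_used, score_value=score_value,
    )


def _parent_index(model, enc, node) -> np.ndarray:
    cards = model.cards()
    parents = model.parents(node)
    idx = np.zeros(next(iter(enc.values())).shape[0], dtype=np.int64)
    for p in parents:
        idx = idx * cards[p] + enc[p]
    return idx


def loglik_loss(model: BayesianNetworkModel, data: pd.DataFrame) -> float:
    """Negative mean per-record log joint probability (natural log)."""
    if not model.cpts:
        raise InputError("model has no fitted CPTs")
    enc = encode_data(data, model.categories)
    total = np.zeros(len(data))
    for v in model.nodes:
        rows = _parent_index(model, enc, v)
        p = np.asarray(model.cpts[v])[rows, enc[v]]
        with np.errstate(divide="ignore"):
            total += np.log(p)
    return float(-np.mean(total))


@dataclass
class ScoreSelectionResult:
    mean_losses: dict          # score name -> mean CV loss
    chosen: str

    def to_dict(self):
        return {"mean_losses": self.mean_losses, "chosen": self.chosen}


def select_scoring_function(data: pd.DataFrame,
                            constraints: StructureConstraints | None = None,
                            folds: int = 10, seed: int = 0,
                            ess: float = 10.0, smoothing: float = 1.0,
                            categories: dict | None = None,
                            scores=SCORES) -> ScoreSelectionResult:
    """Pick the structure score with minimal k-fold CV log-likelihood loss."""
    from .evaluate import kfold_indices

    if folds < 2:
        raise InputError("folds must be >= 2")
    categories = categories or infer_categories(data)
    assignment = kfold_indices(len(data), folds, seed)
    losses = {s: [] for s in scores}
    for k in range(folds):
        train = data[assignment != k]
        valid = data[assignment == k]
        for s in scores:
            structure = hill_climb(train, constraints, score=s, ess=ess,
                                   categories=categories)
            fitted = fit_cpts(structure, train, smoothing=smoothing,
                              categories=categories)
            losses[s].append(loglik_loss(fitted, valid))
    means = {s: float(np.mean(v)) for s, v in losses.items()}
    chosen = min(sorted(means), key=means.get)
    return ScoreSelectionResult(means, chosen)


# ---------------------------------------------------------------------------
# exact inference (variable elimination)


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars, table):
        self.vars = list(vars)
        self.table = np.asarray(table, dtype=float)


def _cpt_factor(model, node) -> _Factor:
    parents = model.parents(node)
    cards = model.cards()
    shape = [cards[p] for p in parents] + [cards[node]]
    table = np.asarray(model.cpts[node]).reshape(shape)
    return _Factor(parents + [node], table)


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    vars_out = f1.vars + [v for v in f2.vars if v not in f1.vars]
    a = f1.table.reshape(f1.table.shape + (1,) * (len(vars_out) - len(f1.vars)))
    b_shape = [1] * len(vars_out)
    for v, s in zip(f2.vars, f2.table.shape):
        b_shape[vars_out.index(v)] = s
    order = sorted(range(len(f2.vars)),
                   key=lambda i: vars_out.index(f2.vars[i]))
    b = np.transpose(f2.table, order).reshape(b_shape)
    return _Factor(vars_out, a * b)


def _sum_out(f: _Factor, var) -> _Factor:
    i = f.vars.index(var)
    return _Factor([v for v in f.vars if v != var], f.table.sum(axis=i))


def predict_class(model: BayesianNetworkModel, evidence: dict,
                  target: str):
    """Exact posterior P(target | evidence) by variable elimination.

    Evidence maps node names to observed state labels; nodes absent from
    ``evidence`` are marginalized. Returns a dict state -> probability.
    """
    if target in evidence:
        raise InputError("evidence must not include the target")
    cards = model.cards()
    factors = []
    for v in model.nodes:
        f = _cpt_factor(model, v)
        factors.append(f)
    # reduce by evidence
    reduced = []
    for f in factors:
        t = f.table
        vars_left = list(f.vars)
        for ev, val in evidence.items():
            if ev in vars_left:
                if val not in model.categories[ev]:
                    raise InputError(f"evidence {ev}={val!r} outside states")
                i = vars_left.index(ev)
                s = model.categories[ev].index(val)
                t = np.take(t, s, axis=i)
                vars_left.pop(i)
        reduced.append(_Factor(vars_left, t))
    # eliminate everything but the target, min-degree-ish fixed order
    hidden = [v for v in model.topological_order()
              if v != target and v not in evidence]
    work = reduced
    for h in hidden:
        involved = [f for f in work if h in f.vars]
        rest = [f for f in work if h not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        work = rest + [_sum_out(prod, h)]
    result = None
    for f in work:
        result = f if result is None else _multiply(result, f)
    if result is None or target not in result.vars:
        raise InputError(f"target {target!r} not in model")
    # collapse scalars
    axis = result.vars.index(target)
    table = result.table
    for i in sorted(range(len(result.vars)), reverse=True):
        if i != axis and result.vars[i] is not None:
            table = table.sum(axis=i)
            if i < axis:
                axis -= 1
    total = table.sum()
    if total <= 0:
        raise InputError("evidence has zero probability under the model")
    post = table / total
    return {s: float(p) for s, p in zip(model.categories[target], post)}


def posterior_table(model: BayesianNetworkModel, data: pd.DataFrame,
                    target: str, evidence_nodes=None) -> np.ndarray:
    """Per-record posterior over target states; rows sum to 1."""
    nodes = evidence_nodes or [v for v in model.nodes if v != target]
    out = np.zeros((len(data), len(model.categories[target])))
    cache: dict = {}
    for i, (_, row) in enumerate(data.iterrows()):
        key = tuple(row[v] for v in nodes)
        if key not in cache:
            ev = {v: row[v] for v in nodes}
            post = predict_class(model, ev, target)
            cache[key] = np.array(
                [post[s] for s in model.categories[target]]
            )
        out[i] = cache[key]
    return out


# ---------------------------------------------------------------------------
# arc strength


@dataclass
class ArcStrengthReport:
    method: str
    arcs: dict      # (a, b) -> {"strength": float, "p_value": float | None}


def arc_strength(model: BayesianNetworkModel, data: pd.DataFrame,
                 method: str = "ci_test", replicates: int = 100,
                 seed: int = 0,
                 constraints: StructureConstraints | None = None,
                 ess: float = 10.0) -> ArcStrengthReport:
    """Per-arc strength.

    * ``score_delta``: network-score loss from removing the arc (positive =
      the arc helps).
    * ``ci_test``: G^2 conditional-independence test of child vs parent
      given the child's other parents; strength is the G^2 statistic.
    * ``bootstrap``: fraction of nonparametric bootstrap relearns (same
      score and constraints) that contain the arc.
    """
    if method not in ("score_delta", "ci_test", "bootstrap"):
        raise InputError(f"unknown method {method!r}")
    categories = model.categories
    arcs: dict = {}
    if method == "score_delta":
        score = model.score_used or "bic"
        full = network_score(model.edges, data, score, ess, categories)
        for a, b in sorted(model.edges):
            reduced = network_score(model.edges - {(a, b)}, data, score,
                                    ess, categories)
            arcs[(a, b)] = {"strength": float(full - reduced),
                            "p_value": None}
    elif method == "ci_test":
        enc = encode_data(data, categories)
        cards = {v: len(c) for v, c in categories.items()}
        for a, b in sorted(model.edges):
            others = [p for p in model.parents(b) if p != a]
            g2, dof = _g2_statistic(enc, a, b, others, cards)
            p = float(stats.chi2.sf(g2, dof)) if dof > 0 else 1.0
            arcs[(a, b)] = {"strength": float(g2), "p_value": p}
    else:
        rng = np.random.default_rng(seed)
        n = len(data)
        score = model.score_used or "bic"
        hits = {e: 0 for e in model.edges}
        for _ in range(replicates):
            idx = rng.integers(n, size=n)
            boot = data.iloc[idx].reset_index(drop=True)
            m = hill_climb(boot, constraints, score=score, ess=ess,
                           categories=categories)
            for e in hits:
                if e in m.edges:
                    hits[e] += 1
        for e, h in hits.items():
            arcs[e] = {"strength": h / replicates, "p_value": None}
    return ArcStrengthReport(method, arcs)


def _g2_statistic(enc, a, b, conditioning, cards):
    """G^2 test of a independent-of b given ``conditioning``."""
    n = enc[a].shape[0]
    strat = np.zeros(n, dtype=np.int64)
    q = 1
    for c in conditioning:
        strat = strat * cards[c] + enc[c]
        q *= cards[c]
    ra, rb = cards[a], cards[b]
    g2 = 0.0
    for s in range(q):
        mask = strat == s
        ns = int(mask.sum())
        if ns == 0:
            continue
        table = np.zeros((ra, rb))
        np.add.at(table, (enc[a][mask], enc[b][mask]), 1.0)
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / ns
        nz = table > 0
        g2 += 2.0 * float(np.sum(table[nz] * np.log(table[nz] / expected[nz])))
    dof = (ra - 1) * (rb - 1) * q
    return g2, dof
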