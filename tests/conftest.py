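"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adbn.bayesnet import BayesianNetworkModel
from adbn.cohort import CohortTable
from adbn.dictionary import default_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


def make_cohort_df(records):
    """Build a minimal cohort DataFrame from (subject, visit, cdr, diag,
    extra-dict) tuples."""
    rows = []
    for subject, visit, cdr, diag, extra in records:
        row = {"subject_id": subject, "visit": visit, "cdr": cdr,
               "diagnosis": diag}
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


def random_network(rng, max_nodes=10, max_states=3, edge_prob=0.3):
    """Random DAG with random strictly-positive CPTs."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"v{i}" for i in range(n)]
    cards = {v: int(rng.integers(2, max_states + 1)) for v in nodes}
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.add((nodes[i], nodes[j]))
    cats = {v: [f"s{k}" for k in range(cards[v])] for v in nodes}
    parents = {v: sorted(a for a, b in edges if b == v) for v in nodes}
    cpts = {}
    for v in nodes:
        q = int(np.prod([cards[p] for p in parents[v]])) if parents[v] else 1
        t = rng.random((q, cards[v])) + 0.05
        cpts[v] = t / t.sum(axis=1, keepdims=True)
    return BayesianNetworkModel(nodes=nodes, categories=cats, edges=edges,
                                cpts=cpts, parent_order=parents)


def brute_force_posterior(net, evidence, target):
    """Posterior by full joint enumeration; the inference oracle."""
    cards = net.cards()
    nodes = net.nodes
    post = np.zeros(cards[target])
    for assign in itertools.product(*[range(cards[v]) for v in nodes]):
        a = dict(zip(nodes, assign))
        if any(net.categories[k].index(v) != a[k]
               for k, v in evidence.items()):
            continue
        p = 1.0
        for v in nodes:
            idx = 0
            for pa in net.parents(v):
                idx = idx * cards[pa] + a[pa]
            p *= net.cpts[v][idx, a[v]]
        post[a[target]] += p
    return post / post.sum()


def exhaustive_single_boundary(values, classes):
    """Best single CAIM boundary by exhaustive search; the greedy oracle."""
    from adbn.discretize import build_quanta_matrix, caim_score

    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    best = (-np.inf, None)
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        q = build_quanta_matrix(values, classes, [cut])
        if np.any(q.column_totals == 0):
            continue
        s = caim_score(q)
        if s > best[0]:
            best = (s, cut)
    return best


@pytest.fixture(scope="session")
def ground_truth_net():
    from adbn.simulate import default_ground_truth_network

    return default_ground_truth_network()
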