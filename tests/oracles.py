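"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — explicit loops, set arithmetic and
exact rational arithmetic where it matters — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# -- ontology ---------------------------------------------------------------


def reachable_fixpoint(edges: dict[str, set[str]], start: str) -> set[str]:
    """Ancestors by repeated one-step edge expansion to a fixpoint."""
    out: set[str] = set()
    frontier = set(edges.get(start, set()))
    while frontier:
        out |= frontier
        nxt = set()
        for t in frontier:
            nxt |= edges.get(t, set())
        frontier = nxt - out
    return out


def propagate_sets(edges: dict[str, set[str]], prot_terms: dict[str, set[str]]):
    """Per-protein union of each term with its fixpoint ancestors."""
    return {
        p: set().union(*({t} | reachable_fixpoint(edges, t) for t in ts))
        for p, ts in prot_terms.items()
    }


def count_filter(prot_terms: dict[str, set[str]], min_count: int) -> set[str]:
    counts: dict[str, int] = {}
    for ts in prot_terms.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    return {t for t, c in counts.items() if c >= min_count}


def ic_by_intersection(
    edges: dict[str, set[str]], prot_terms: dict[str, set[str]], term: str
) -> float:
    parents = edges.get(term, set())
    n_c = sum(1 for ts in prot_terms.values() if term in ts)
    if parents:
        n_p = sum(1 for ts in prot_terms.values() if parents <= ts)
    else:
        n_p = len(prot_terms)
    return -math.log(n_c / n_p)


# -- grouping ---------------------------------------------------------------


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_unionfind(nodes, edges) -> list[frozenset]:
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return sorted((frozenset(g) for g in groups.values()), key=min)


# -- risks ------------------------------------------------------------------


def neg_log_sigmoid(z: float) -> float:
    # ln(1 + e^-z) without overflow
    if z >= 0:
        return math.log1p(math.exp(-z))
    return -z + math.log1p(math.exp(z))


def risk_components_loop(logits, labels):
    pos = [g for g, y in zip(logits, labels) if y]
    unl = [g for g, y in zip(logits, labels) if not y]
    rpp = sum(neg_log_sigmoid(g) for g in pos) / len(pos) if pos else None
    rpm = sum(neg_log_sigmoid(-g) for g in pos) / len(pos) if pos else None
    rum = sum(neg_log_sigmoid(-g) for g in unl) / len(unl) if unl else None
    return rpp, rpm, rum


def ranking_risk_loop(logits, labels):
    pos = [g for g, y in zip(logits, labels) if y]
    unl = [g for g, y in zip(logits, labels) if not y]
    if not pos or not unl:
        return None
    total = sum(neg_log_sigmoid(x - y) for x in pos for y in unl)
    return total / (len(pos) * len(unl))


def bce_loop(logits, labels):
    total = 0.0
    n = 0
    for row_g, row_y in zip(logits, labels):
        for g, y in zip(row_g, row_y):
            total += neg_log_sigmoid(g) if y else neg_log_sigmoid(-g)
            n += 1
    return total / n


def multilabel_risk_loop(logits, labels, pi, beta, ranking, clamp=True):
    """Per-class recomputation of the summed clamped risk; skips empty sides."""
    total = 0.0
    contributing = 0
    for j in range(logits.shape[1]):
        col = list(logits[:, j])
        lab = list(labels[:, j])
        rpp, rpm, _ = risk_components_loop(col, lab)
        ru = ranking_risk_loop(col, lab) if ranking else risk_components_loop(col, lab)[2]
        if rpp is None or ru is None:
            continue
        contributing += 1
        inner = ru - pi[j] * rpm + beta[j]
        if clamp:
            total += pi[j] * rpp + max(0.0, inner)
        else:
            total += pi[j] * rpp - pi[j] * rpm + ru
    return total, contributing


# -- metrics ----------------------------------------------------------------


def curve_points_sets(scores, truth, thresholds):
    """(AvgPr, AvgRc, m) per threshold by explicit set arithmetic."""
    n_prot, _ = scores.shape
    truth_sets = [set(np.flatnonzero(truth[i])) for i in range(n_prot)]
    with_truth = [i for i in range(n_prot) if truth_sets[i]]
    out = []
    for t in thresholds:
        pred_sets = [
            set(np.flatnonzero((scores[i] >= t) & (scores[i] > 0)))
            for i in range(n_prot)
        ]
        preds = [i for i in range(n_prot) if pred_sets[i]]
        m = len(preds)
        if m:
            avg_pr = sum(
                Fraction(len(pred_sets[i] & truth_sets[i]), len(pred_sets[i]))
                for i in preds
            ) / m
        else:
            avg_pr = None
        if with_truth:
            avg_rc = sum(
                Fraction(len(pred_sets[i] & truth_sets[i]), len(truth_sets[i]))
                for i in with_truth
            ) / len(with_truth)
        else:
            avg_rc = Fraction(0)
        out.append((avg_pr, avg_rc, m))
    return out


def fmax_exhaustive(scores, truth, thresholds):
    best = Fraction(0)
    best_t = None
    found = False
    for t, (pr, rc, m) in zip(thresholds, curve_points_sets(scores, truth, thresholds)):
        if pr is None:
            continue
        found = True
        f = Fraction(0) if pr + rc == 0 else 2 * pr * rc / (pr + rc)
        if best_t is None or f > best:
            best, best_t = f, t
    if not found:
        return 0.0, None
    return float(best), best_t


def smin_sets(scores, truth, ic, thresholds):
    n = scores.shape[0]
    best = math.inf
    for t in thresholds:
        ru = mi = 0.0
        for i in range(n):
            pred = set(np.flatnonzero((scores[i] >= t) & (scores[i] > 0)))
            ts = set(np.flatnonzero(truth[i]))
            ru += sum(ic[c] for c in ts - pred)
            mi += sum(ic[c] for c in pred - ts)
        best = min(best, math.hypot(ru / n, mi / n))
    return best


def trapezoid_loop(xs, ys) -> float:
    pts = sorted(zip(xs, ys))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def auc_pair_counting(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# -- baselines --------------------------------------------------------------


def diamond_vote_loop(hit_rows, subject_terms, query, terms, e_max=0.001):
    """Weighted homology vote for one query over an explicit term list."""
    kept = [
        (s, bits)
        for (q, s, ev, bits) in hit_rows
        if q == query and ev <= e_max and s in subject_terms
    ]
    denom = sum(b for _, b in kept)
    out = {}
    for f in terms:
        num = sum(b for s, b in kept if f in subject_terms[s])
        out[f] = num / denom if denom else 0.0
    return out
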