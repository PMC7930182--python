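"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use brute-force enumeration or closed forms,
independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cx3score import Repertoire, build_table1_fixture, simulate_cohort
from cx3score.synthetic import CohortSpec


@pytest.fixture(scope="session")
def table1_cohort():
    return build_table1_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortSpec(n_patients=60, seed=11))


@pytest.fixture()
def toy_repertoire():
    df = pd.DataFrame({
        "nucleotide": ["TGTGCA", "TGTGCC", "TGTGCG", "TGTGCT", "TGTGAA"],
        "amino_acid": ["CASSLF", "CASSLF", "CASTYF", "CASQPF", ""],
        "count": [40, 10, 30, 15, 5],
        "v_gene": "TRBV05", "j_gene": "TRBJ1-1",
        "status": ["In", "In", "In", "In", "Out"],
    })
    return Repertoire.from_counts(df)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def auc_pair_counting(scores, labels):
    """P(responder score > non-responder) + half credit for ties, all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    wins = ties = total = 0
    for x in scores[labels]:
        for y in scores[~labels]:
            total += 1
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / total


def youden_brute_force(scores, labels):
    """Exhaustive search over distinct observed scores, smallest-cutoff ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best_j, best_c = -np.inf, None
    for c in np.unique(scores):
        pos = scores >= c
        j = pos[labels].mean() + (~pos[~labels]).mean() - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def fisher_enumeration(tp, fp, fn, tn):
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    row1, row2 = tp + fn, fp + tn
    col1 = tp + fp
    n = row1 + row2

    def prob(a):
        return (math.comb(row1, a) * math.comb(row2, col1 - a)) / math.comb(n, col1)

    p_obs = prob(tp)
    total = 0.0
    for a in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def mannwhitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p over all C(nA+nB, nA) group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= dev_obs - 1e-9:
            count += 1
    return u_obs, count / total


def align_enumeration(a, b, sub, gap):
    """Optimal global alignment score by exhaustive recursion over all paths."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub[a[i], b[j]] + rec(i + 1, j + 1))
        if i < len(a):
            options.append(-gap + rec(i + 1, j))
        if j < len(b):
            options.append(-gap + rec(i, j + 1))
        return max(options)

    return rec(0, 0)


def gini_pairwise(values):
    """Mean absolute difference definition of the Gini index."""
    f = np.asarray(values, float)
    r = len(f)
    return float(np.abs(f[:, None] - f[None, :]).sum() / (2 * r * r * f.mean()))


def km_by_hand(times, events):
    """Product-limit estimate as explicit (time, survival) steps."""
    out, s = [], 1.0
    for t in sorted(set(times)):
        at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        if d:
            s *= (at_risk - d) / at_risk
        out.append((t, s))
    return out


def logrank_by_hand(ta, ea, tb, eb):
    """O/E/V tabulation over pooled event times (hypergeometric variance)."""
    event_times = sorted({t for t, e in list(zip(ta, ea)) + list(zip(tb, eb)) if e == 1})
    oa = exp_a = var = 0.0
    for t in event_times:
        na = sum(1 for x in ta if x >= t)
        nb = sum(1 for x in tb if x >= t)
        da = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        db = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = na + nb, da + db
        oa += da
        exp_a += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return oa, exp_a, var
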