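import math

import numpy as np
import pytest

from selfscape.core_data import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CALL_DTYPE,
    GenotypeTable,
    SnpPanel,
)


@pytest.fixture
def tiny_table():
    """3 samples x 2 markers, hand-written."""
    panel = SnpPanel.minimal(["m1", "m2"])
    calls = np.array([[0, 2], [1, -1], [2, 2]], dtype=CALL_DTYPE)
    return GenotypeTable(panel, ["a", "b", "c"], calls)


def make_table(calls, sample_ids=None):
    calls = np.asarray(calls, dtype=CALL_DTYPE)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeTable(SnpPanel.minimal(
        [f"m{j}" for j in range(calls.shape[1])]), list(sample_ids), calls)


def random_table(rng, n_samples, n_markers, p_missing=0.05, p_het=0.05):
    u = rng.random((n_samples, n_markers))
    calls = np.where(u < 0.45, HOM_REF, HOM_ALT).astype(CALL_DTYPE)
    calls[rng.random(calls.shape) < p_het] = HET
    calls[rng.random(calls.shape) < p_missing] = MISSING
    return make_table(calls)


# --------------------------------------------------------------------------
# Independent oracles (pure-python, no shared code with the implementation)
# --------------------------------------------------------------------------

def binom_tail_oracle(k, n, eps):
    """P(X >= k) by direct summation of binomial pmf terms."""
    return sum(
        math.comb(n, i) * eps**i * (1 - eps) ** (n - i) for i in range(k, n + 1)
    )


def mismatch_oracle(h1, h2, het_as_missing=True):
    """(k, n) by a literal per-position loop."""
    k = n = 0
    for a, b in zip(h1, h2):
        bad = {MISSING, HET} if het_as_missing else {MISSING}
        if a in bad or b in bad:
            continue
        n += 1
        if a != b:
            k += 1
    return k, n


def distance_oracle(h1, h2, eps=0.005):
    k, n = mismatch_oracle(h1, h2)
    if n == 0:
        return float("inf")
    return -math.log10(binom_tail_oracle(k, n, eps))


def grow_oracle(center, candidates, dist_fn, alpha=0.05, rule="SIZE_MULTIPLICATIVE"):
    """Literal greedy walk: propose by ascending distance, include while
    d < tau(current size), stop at first failure."""
    cand = sorted(candidates)
    d = [(dist_fn(center, c), i, c) for i, c in enumerate(cand)]
    d.sort()
    members = [center]
    for dd, _, c in d:
        m = len(members)
        if rule == "SIZE_MULTIPLICATIVE":
            tau = alpha * m
        elif rule == "SIZE_BONFERRONI":
            tau = alpha / m
        else:
            tau = alpha
        if dd < tau:
            members.append(c)
        else:
            break
    return members


def qt_cluster_oracle(calls, eps=0.005, alpha=0.05):
    """Exhaustive re-evaluating QT clustering: every remaining sample is
    literally retried as center each round; no dedup shortcut."""
    n = len(calls)
    cache = {}

    def dist_fn(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = distance_oracle(calls[i], calls[j], eps)
        return cache[key]

    remaining = list(range(n))
    groups = []
    while remaining:
        best = None
        for center in remaining:
            members = grow_oracle(
                center, [c for c in remaining if c != center], dist_fn, alpha
            )
            size = len(members)
            total = sum(dist_fn(center, m) for m in members[1:])
            key = (-size, total, center)
            if best is None or key < best[0]:
                best = (key, members)
        groups.append(best[1])
        taken = set(best[1])
        remaining = [r for r in remaining if r not in taken]
    return groups
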