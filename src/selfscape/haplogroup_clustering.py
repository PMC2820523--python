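"""Haplogroup assignment by modified QT clustering.

Every plant is placed in exactly one haplogroup of "potentially
identical" haplotypes.  The distance between two haplotypes is derived
from the binomial tail probability of seeing the observed number (or
more) of marker mismatches if the two were truly identical and each
compared marker disagreed independently with a small probability
epsilon (the per-marker genotyping discrepancy rate):

    q = P(X >= k),  X ~ Binomial(n, epsilon)

with k mismatches over n both-informative markers.  Identical
haplotypes give q = 1; each extra mismatch shrinks q sharply.  The
default distance is d = -log10(q), which is 0 for identical haplotypes
and grows without bound, so the cluster-size-adaptive threshold
("include while distance < alpha * current cluster size") tolerates a
few genotyping errors inside large clonal groups while never merging
unrelated haplotypes.  A bounded d = 1 - q transform and alternative
threshold rules are kept as configuration for sensitivity analysis.

Clustering proceeds greedily: every remaining sample is tried as a
center, the center producing the largest cluster wins (ties broken by
smaller total member distance, then by input order), the winning
cluster is removed, and the search repeats until no sample remains.
Heterozygous calls are treated as missing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core_data import GenotypeTable, mismatch_matrix, pairwise_mismatch

ThresholdRule = Literal["SIZE_MULTIPLICATIVE", "SIZE_BONFERRONI", "FIXED"]
DistanceTransform = Literal["NEG_LOG10_TAIL", "ONE_MINUS_TAIL"]


@dataclass(frozen=True)
class ClusterParams:
    """Tunables of the clustering.

    error_rate: per-marker discrepancy probability under the identity
    hypothesis (default 0.005, i.e. one bad call per 200 markers).
    alpha: threshold multiplier in the inclusion rule (default 0.05).
    """

    error_rate: float = 0.005
    alpha: float = 0.05
    threshold_rule: ThresholdRule = "SIZE_MULTIPLICATIVE"
    distance_transform: DistanceTransform = "NEG_LOG10_TAIL"
    het_as_missing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError("error_rate must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class HaplogroupAssignment:
    """A complete partition of samples into haplogroups."""

    group_of: dict[str, str]
    central_of: dict[str, str]
    extraction_order: list[str]
    distance_to_central: dict[str, float] = field(default_factory=dict)

    def members(self, group_id: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group_id]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.group_of.values():
            out[g] = out.get(g, 0) + 1
        return out

    @property
    def n_groups(self) -> int:
        return len(self.central_of)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, g in self.group_of.items():
            rows.append(
                {
                    "sample_id": s,
                    "haplogroup_id": g,
                    "is_central": s == self.central_of[g],
                    "distance_to_central": self.distance_to_central.get(s, np.nan),
                }
            )
        return pd.DataFrame(rows)

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "HaplogroupAssignment":
        group_of = dict(zip(frame["sample_id"], frame["haplogroup_id"]))
        central_of = {
            r["haplogroup_id"]: r["sample_id"]
            for _, r in frame.iterrows()
            if r["is_central"]
        }
        order = list(dict.fromkeys(frame["haplogroup_id"]))
        dist = dict(zip(frame["sample_id"], frame.get("distance_to_central", [])))
        return HaplogroupAssignment(group_of, central_of, order, dist)


def identity_tail_probability(k, n, error_rate: float):
    """P(X >= k) for X ~ Binomial(n, error_rate), computed via the
    survival function for numerical stability.  Accepts arrays."""
    k = np.asarray(k)
    n = np.asarray(n)
    if (k < 0).any() or (k > n).any():
        raise ValueError("need 0 <= k <= n")
    if (n < 1).any():
        raise ValueError("n must be >= 1; pairs with no comparable marker "
                         "are unclusterable")
    out = binom.sf(k - 1, n, error_rate)
    return float(out) if out.ndim == 0 else out


def pair_distance(h1, h2, params: ClusterParams = ClusterParams()) -> float:
    """Distance between two call vectors under the binomial-identity model.

    Returns +inf when the pair shares no comparable marker.
    """
    pm = pairwise_mismatch(h1, h2, het_as_missing=params.het_as_missing)
    if pm.n == 0:
        return float("inf")
    q = identity_tail_probability(pm.k, pm.n, params.error_rate)
    return _transform(np.asarray(q), params.distance_transform).item()


def _transform(q: np.ndarray, transform: DistanceTransform) -> np.ndarray:
    if transform == "NEG_LOG10_TAIL":
        with np.errstate(divide="ignore"):
            return -np.log10(q)
    if transform == "ONE_MINUS_TAIL":
        return 1.0 - q
    raise ValueError(f"unknown distance transform {transform!r}")


def distance_matrix(gt: GenotypeTable, params: ClusterParams) -> np.ndarray:
    """All-pairs distance matrix; +inf marks incomparable pairs (n = 0)."""
    k_mat, n_mat = mismatch_matrix(gt.calls, het_as_missing=params.het_as_missing)
    d = np.full(k_mat.shape, np.inf)
    ok = n_mat > 0
    q = binom.sf(k_mat[ok] - 1, n_mat[ok], params.error_rate)
    d[ok] = _transform(q, params.distance_transform)
    np.fill_diagonal(d, 0.0)
    return d


def _thresholds(n_candidates: int, params: ClusterParams) -> np.ndarray:
    """tau for the j-th proposed candidate (j = 1..n), evaluated at the
    cluster size m = j current when that candidate is tested (center
    counts, so the first candidate sees m = 1)."""
    m = np.arange(1, n_candidates + 1, dtype=float)
    if params.threshold_rule == "SIZE_MULTIPLICATIVE":
        return params.alpha * m
    if params.threshold_rule == "SIZE_BONFERRONI":
        return params.alpha / m
    if params.threshold_rule == "FIXED":
        return np.full(n_candidates, params.alpha)
    raise ValueError(f"unknown threshold rule {params.threshold_rule!r}")


def grow_cluster(
    center: int,
    candidates: Sequence[int],
    dist: np.ndarray,
    params: ClusterParams = ClusterParams(),
) -> list[int]:
    """Grow one cluster around ``center`` from ``candidates``.

    Candidates are proposed in order of ascending distance to the center
    (ties by ascending index) and included while distance < tau(current
    cluster size); the walk stops at the first failure.  Returns the
    member list, center first, in inclusion order.
    """
    cand = np.asarray(sorted(candidates))
    if center in cand:
        raise ValueError("center must not be among candidates")
    d = dist[center, cand]
    order = np.argsort(d, kind="stable")
    tau = _thresholds(len(cand), params)
    members = [center]
    for j, idx in enumerate(order):
        if d[idx] < tau[j]:
            members.append(int(cand[idx]))
        else:
            break
    return members


def qt_cluster(
    gt: GenotypeTable, params: ClusterParams = ClusterParams()
) -> HaplogroupAssignment:
    """Partition all samples into haplogroups.

    Each round evaluates every remaining sample as a candidate center,
    keeps the center whose grown cluster is largest (ties: smallest sum
    of member distances to the center, then lowest input index), records
    the winning cluster, removes it, and repeats.  Cluster sizes are
    non-increasing along the extraction order.

    The center search is vectorised: with rows of the remaining distance
    matrix sorted ascending, the cluster a center would grow is the
    longest prefix with d_(j) < tau(j); this is exactly the greedy walk
    of :func:`grow_cluster` applied to every center at once.
    """
    n = gt.n_samples
    if n == 0:
        raise ValueError("need at least one sample")
    dist = distance_matrix(gt, params)

    remaining = np.arange(n)
    group_of: dict[str, str] = {}
    central_of: dict[str, str] = {}
    extraction_order: list[str] = []
    distance_to_central: dict[str, float] = {}
    gid = 0

    while remaining.size:
        r = remaining.size
        sub = dist[np.ix_(remaining, remaining)]
        np.fill_diagonal(sub, np.inf)  # a center is not its own candidate
        order = np.argsort(sub, axis=1, kind="stable")
        dsorted = np.take_along_axis(sub, order, axis=1)
        ncand = r - 1
        if ncand:
            tau = _thresholds(ncand, params)
            ok = dsorted[:, :ncand] < tau[None, :]
            # length of the True prefix of each row
            fail = np.argmin(ok, axis=1)
            all_ok = ok.all(axis=1)
            counts = np.where(all_ok, ncand, fail)
            with np.errstate(invalid="ignore"):
                csum = np.cumsum(
                    np.where(np.isfinite(dsorted[:, :ncand]), dsorted[:, :ncand], 0.0),
                    axis=1,
                )
            sums = np.where(counts > 0, csum[np.arange(r), np.maximum(counts - 1, 0)], 0.0)
        else:
            counts = np.zeros(1, dtype=int)
            sums = np.zeros(1)

        sizes = counts + 1
        best_size = sizes.max()
        tied = np.flatnonzero(sizes == best_size)
        winner = tied[np.argmin(sums[tied])]  # argmin takes first on ties

        center_global = int(remaining[winner])
        member_local = order[winner, : counts[winner]] if ncand else np.empty(0, int)
        members_global = [center_global] + [int(remaining[i]) for i in member_local]

        gname = f"HG{gid + 1:04d}"
        gid += 1
        center_id = gt.sample_ids[center_global]
        central_of[gname] = center_id
        extraction_order.append(gname)
        for m in members_global:
            sid = gt.sample_ids[m]
            group_of[sid] = gname
            distance_to_central[sid] = float(dist[center_global, m])

        keep = np.ones(r, dtype=bool)
        local_members = np.concatenate(([winner], member_local)).astype(int)
        keep[local_members] = False
        remaining = remaining[keep]

    return HaplogroupAssignment(
        group_of=group_of,
        central_of=central_of,
        extraction_order=extraction_order,
        distance_to_central=distance_to_central,
    )


def haplogroup_size_spectrum(assignment: HaplogroupAssignment) -> pd.DataFrame:
    """Table of (size, n_groups); total mass equals the sample count."""
    sizes = pd.Series(list(assignment.sizes().values()))
    spectrum = sizes.value_counts().sort_index(ascending=False)
    return pd.DataFrame({"size": spectrum.index, "n_groups": spectrum.values})
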