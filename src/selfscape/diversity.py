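"""Haplogroup diversity within field sites, the global pairwise mismatch
distribution, and the panmixia resampling simulation.

The mismatch distribution over all plant pairs is the sample's
relatedness fingerprint: genetically identical pairs sit at zero,
unrelated pairs at the allele-frequency-driven background, and pairs of
intermediate relatedness in between.  The panmictic simulation provides
the null background: haplotypes built marker-by-marker by copying calls
from randomly chosen observed donors, which preserves marginal call
frequencies but destroys all linkage and geographic structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    EURASIA,
    NORTH_AMERICA,
    CALL_DTYPE,
    GenotypeTable,
    _informative,
    mismatch_matrix,
)

INTERCONTINENTAL = "INTERCONTINENTAL"
ALL = "ALL"
SIMULATED = "SIMULATED"


@dataclass(frozen=True)
class SiteDiversity:
    """Probability that two plants drawn (without replacement) from one
    site belong to different haplogroups."""

    site_id: str
    n_plants: int
    diversity: float


@dataclass
class MismatchDistribution:
    """Pairwise mismatch fractions for one stratum of pairs.

    Keeps the raw per-pair fractions and mismatch counts alongside the
    histogram so classification rules can be applied downstream.
    ``n_undefined`` counts pairs with no comparable marker, which are
    excluded everywhere.
    """

    stratum: str
    fractions: np.ndarray
    ks: np.ndarray
    bin_edges: np.ndarray
    n_undefined: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.fractions)

    @property
    def histogram(self) -> np.ndarray:
        h, _ = np.histogram(self.fractions, bins=self.bin_edges)
        return h


def default_bin_edges(n_markers: int = 139) -> np.ndarray:
    """Histogram bins one marker wide on the mismatch-fraction axis."""
    return np.arange(0, n_markers + 2) / n_markers


def site_diversity(group_counts) -> float:
    """1 - P(two plants drawn without replacement share a haplogroup).

    ``group_counts`` are the haplogroup multiplicities at one site;
    requires at least two plants.
    """
    c = np.asarray(list(group_counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("site diversity needs at least 2 plants")
    return float(1.0 - (c * (c - 1)).sum() / (n * (n - 1)))


def site_diversity_table(meta: pd.DataFrame, assignment) -> pd.DataFrame:
    """Per-site diversity for every site with >= 2 assigned plants."""
    group_of = assignment.group_of
    rows = []
    for site_id, sub in meta.groupby("site_id", sort=True):
        groups = [group_of[s] for s in sub["sample_id"] if s in group_of]
        if len(groups) < 2:
            continue
        counts = pd.Series(groups).value_counts()
        rows.append(
            {
                "site_id": site_id,
                "n_plants": len(groups),
                "n_haplogroups": len(counts),
                "diversity": site_diversity(counts.values),
                "modal_fraction": counts.max() / len(groups),
                "continent": sub["continent"].iloc[0],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "n_plants", "n_haplogroups", "diversity",
            "modal_fraction", "continent",
        ],
    )


def dominance_summary(
    diversity_table: pd.DataFrame, dominance_threshold: float = 0.8
) -> pd.DataFrame:
    """Fraction of sites whose modal haplogroup exceeds the threshold,
    overall and per continent."""
    if not (0.0 < dominance_threshold < 1.0):
        raise ValueError("dominance_threshold must be in (0, 1)")
    rows = []
    dom = diversity_table["modal_fraction"] > dominance_threshold
    rows.append(
        {
            "continent": ALL,
            "n_sites": len(diversity_table),
            "fraction_dominated": float(dom.mean()) if len(dom) else float("nan"),
        }
    )
    for cont, sub in diversity_table.groupby("continent", sort=True):
        d = sub["modal_fraction"] > dominance_threshold
        rows.append(
            {
                "continent": cont,
                "n_sites": len(sub),
                "fraction_dominated": float(d.mean()),
            }
        )
    return pd.DataFrame(rows)


def _pair_arrays(gt: GenotypeTable, het_as_missing: bool = True):
    """Flattened upper-triangle (k, n) arrays over all unordered pairs."""
    k_mat, n_mat = mismatch_matrix(gt.calls, het_as_missing=het_as_missing)
    iu = np.triu_indices(gt.n_samples, k=1)
    return k_mat[iu], n_mat[iu], iu


def mismatch_distribution(
    gt: GenotypeTable,
    meta: pd.DataFrame | None = None,
    het_as_missing: bool = True,
    bin_edges: np.ndarray | None = None,
) -> dict[str, MismatchDistribution]:
    """Mismatch distribution over all unordered pairs, stratified by the
    continent pair when metadata is given.

    Strata: within-Eurasia, within-North-America, intercontinental, and
    the pooled ALL stratum.  Pairs with no comparable marker are dropped
    and counted per stratum.
    """
    if gt.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if bin_edges is None:
        bin_edges = default_bin_edges(gt.n_markers)
    ks, ns, iu = _pair_arrays(gt, het_as_missing)
    defined = ns > 0
    frac = np.full(len(ks), np.nan)
    frac[defined] = ks[defined] / ns[defined]

    strata: dict[str, np.ndarray] = {ALL: np.ones(len(ks), dtype=bool)}
    if meta is not None:
        cont = meta.set_index("sample_id")["continent"]
        c = np.asarray([cont[s] for s in gt.sample_ids])
        c1, c2 = c[iu[0]], c[iu[1]]
        strata[EURASIA] = (c1 == EURASIA) & (c2 == EURASIA)
        strata[NORTH_AMERICA] = (c1 == NORTH_AMERICA) & (c2 == NORTH_AMERICA)
        strata[INTERCONTINENTAL] = c1 != c2

    out = {}
    for name, mask in strata.items():
        m = mask & defined
        out[name] = MismatchDistribution(
            stratum=name,
            fractions=frac[m],
            ks=ks[m],
            bin_edges=bin_edges,
            n_undefined=int((mask & ~defined).sum()),
        )
    return out


def simulate_panmixia(
    gt: GenotypeTable,
    n_sim: int = 10_000,
    unique_only: bool = False,
    assignment=None,
    seed: int | np.random.Generator = 0,
    het_as_missing: bool = True,
    bin_edges: np.ndarray | None = None,
    max_pairs: int | None = None,
) -> tuple[np.ndarray, MismatchDistribution]:
    """Simulate haplotypes under global random mating.

    Each simulated haplotype copies, independently at every marker, the
    call of a donor plant chosen uniformly with replacement (the donor is
    redrawn per marker).  With ``unique_only`` the donor pool holds one
    representative per haplogroup (its central sample), removing the
    weight of clonally amplified haplotypes.  Returns the simulated call
    matrix and the mismatch distribution over its pairs (all pairs, or a
    uniform subsample of ``max_pairs``).
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if unique_only:
        if assignment is None:
            raise ValueError("unique_only requires a haplogroup assignment")
        reps = set(assignment.central_of.values())
        donor_idx = [i for i, s in enumerate(gt.sample_ids) if s in reps]
    else:
        donor_idx = list(range(gt.n_samples))
    pool = gt.calls[donor_idx]
    L = gt.n_markers
    choice = rng.integers(0, len(donor_idx), size=(n_sim, L))
    sim = pool[choice, np.arange(L)[None, :]].astype(CALL_DTYPE)

    if bin_edges is None:
        bin_edges = default_bin_edges(L)

    if max_pairs is not None and n_sim * (n_sim - 1) // 2 > max_pairs:
        i = rng.integers(0, n_sim, size=2 * max_pairs)
        j = rng.integers(0, n_sim, size=2 * max_pairs)
        keep = i < j
        i, j = i[keep][:max_pairs], j[keep][:max_pairs]
        m1 = _informative(sim[i], het_as_missing)
        m2 = _informative(sim[j], het_as_missing)
        both = m1 & m2
        ns = both.sum(axis=1)
        ks = ((sim[i] != sim[j]) & both).sum(axis=1)
    else:
        ks_all, ns_all = [], []
        chunk = max(1, 2_000_000 // max(n_sim, 1))
        for lo in range(0, n_sim, chunk):
            hi = min(lo + chunk, n_sim)
            k_mat, n_mat = _chunk_mismatch(sim, lo, hi, het_as_missing)
            for r in range(lo, hi):
                ks_all.append(k_mat[r - lo, r + 1:])
                ns_all.append(n_mat[r - lo, r + 1:])
        ks = np.concatenate(ks_all) if ks_all else np.empty(0, int)
        ns = np.concatenate(ns_all) if ns_all else np.empty(0, int)

    defined = ns > 0
    dist = MismatchDistribution(
        stratum=SIMULATED,
        fractions=(ks[defined] / ns[defined]),
        ks=ks[defined],
        bin_edges=bin_edges,
        n_undefined=int((~defined).sum()),
    )
    return sim, dist


def _chunk_mismatch(sim: np.ndarray, lo: int, hi: int, het_as_missing: bool):
    """Mismatch counts of rows [lo, hi) against all rows."""
    m = _informative(sim, het_as_missing).astype(np.float64)
    a = (sim == 2).astype(np.float64) * m  # HOM_ALT indicator over informative
    mc, ac = m[lo:hi], a[lo:hi]
    n_mat = mc @ m.T
    k_mat = ac @ m.T + mc @ a.T - 2.0 * (ac @ a.T)
    return np.rint(k_mat).astype(np.int64), np.rint(n_mat).astype(np.int64)


def expected_panmictic_mismatch(
    gt: GenotypeTable,
    unique_only: bool = False,
    assignment=None,
    het_as_missing: bool = True,
) -> float:
    """Closed-form expectation of the panmictic mean mismatch fraction.

    At marker j let f_c be the donor-pool frequency of informative call
    c and g_j the total informative frequency.  Two independently drawn
    calls are both informative with probability g_j^2 and differ with
    probability g_j^2 - sum_c f_c^2.  The mean pair fraction is
    approximated by the ratio of expectations sum_j (g_j^2 - sum f_c^2)
    / sum_j g_j^2, accurate because the comparable-marker count
    concentrates tightly around its mean.
    """
    if unique_only:
        reps = set(assignment.central_of.values())
        donor_idx = [i for i, s in enumerate(gt.sample_ids) if s in reps]
    else:
        donor_idx = list(range(gt.n_samples))
    pool = gt.calls[donor_idx]
    m = _informative(pool, het_as_missing)
    n_donors = len(donor_idx)
    num = 0.0
    den = 0.0
    for j in range(gt.n_markers):
        col = pool[:, j][m[:, j]]
        g = len(col) / n_donors
        if g == 0:
            continue
        _, cnt = np.unique(col, return_counts=True)
        f2 = ((cnt / n_donors) ** 2).sum()
        num += g * g - f2
        den += g * g
    return num / den if den > 0 else float("nan")


def classify_pairs(
    observed: MismatchDistribution,
    simulated: MismatchDistribution,
    unrelated_quantile: float = 1.0,
) -> dict[str, float]:
    """Split observed pairs into identical / intermediate / unrelated.

    IDENTICAL: zero mismatches over the compared markers.  UNRELATED:
    mismatch fraction at or above the ``unrelated_quantile``-th
    percentile of the simulated panmictic distribution (default the 1st
    percentile, i.e. anything not clearly below the panmictic
    background).  Everything else is INTERMEDIATE.  Fractions sum to 1
    over defined pairs.
    """
    if simulated.n_pairs == 0:
        raise ValueError("simulated distribution is empty")
    cut = float(np.percentile(simulated.fractions, unrelated_quantile))
    n = observed.n_pairs
    if n == 0:
        return {"identical": float("nan"), "intermediate": float("nan"),
                "unrelated": float("nan"), "cutoff": cut}
    identical = observed.ks == 0
    unrelated = (~identical) & (observed.fractions >= cut)
    f_id = identical.mean()
    f_un = unrelated.mean()
    return {
        "identical": float(f_id),
        "intermediate": float(1.0 - f_id - f_un),
        "unrelated": float(f_un),
        "cutoff": cut,
    }
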