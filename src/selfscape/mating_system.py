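"""Per-field-site inbreeding coefficient and selfing rate.

Under a mixed-mating model at inbreeding equilibrium, a fraction F of
the Hardy-Weinberg heterozygosity is lost.  F_IS measures that deficit
within a site; a constant selfing rate s that produces an equilibrium
inbreeding coefficient F satisfies F = s/(2-s), inverted here as

    s = 2 / (1/F_IS + 1) = 2 * F_IS / (1 + F_IS).

F_IS is estimated per site as the multilocus ratio of sums

    F_IS = 1 - sum_j H_obs,j / sum_j H_exp,j

over loci polymorphic within the site, where H_obs,j is the observed
heterozygote fraction at locus j and H_exp,j = 2 p_j (1 - p_j) *
2n_j/(2n_j - 1) is the small-sample-corrected expected heterozygosity
from the within-site allele frequency p_j over the n_j plants with
non-missing calls.  Negative F_IS (heterozygote excess) maps to a
selfing rate clamped at 0.

Confidence intervals come from a locus bootstrap: loci are resampled
with replacement and the F_IS -> s chain recomputed per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    FIELD_MATURE,
    FIELD_SEED_GROWN,
    HET,
    HOM_ALT,
    MISSING,
    GenotypeTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteMatingEstimate:
    site_id: str
    fis: float  # NaN when undefined
    selfing: float  # NaN when undefined
    ci_low: float
    ci_high: float
    n_plants: int
    n_loci_used: int


def _locus_components(calls: np.ndarray) -> pd.DataFrame:
    """Per-locus H_obs / H_exp components over polymorphic loci.

    ``calls`` is the (n_plants, L) matrix of one site.  Loci monomorphic
    within the site (p in {0, 1}) or with fewer than 2 non-missing calls
    contribute nothing and are excluded.
    """
    calls = np.asarray(calls)
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    n_het = ((calls == HET) & nonmiss).sum(axis=0)
    alt_count = (2 * (calls == HOM_ALT) + (calls == HET)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_count / (2 * n)
        h_obs = n_het / n
        h_exp = 2 * p * (1 - p) * (2 * n / (2 * n - 1))
    poly = (n >= 2) & (p > 0) & (p < 1)
    idx = np.flatnonzero(poly)
    return pd.DataFrame(
        {
            "locus": idx,
            "n": n[idx].astype(int),
            "p_hat": p[idx],
            "h_obs": h_obs[idx],
            "h_exp": h_exp[idx],
        }
    )


def site_fis(calls: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Multilocus F_IS for one site (ratio of sums across loci).

    Returns (F_IS, per-locus component table); F_IS is NaN when no locus
    is polymorphic within the site.
    """
    calls = np.asarray(calls)
    if calls.shape[0] < 2:
        raise ValueError("site_fis needs at least 2 plants")
    comp = _locus_components(calls)
    if comp.empty:
        return float("nan"), comp
    fis = 1.0 - comp["h_obs"].sum() / comp["h_exp"].sum()
    return float(fis), comp


def selfing_from_fis(fis: float) -> float:
    """Selfing rate s = 2/(1/F_IS + 1), clamped to [0, 1].

    Non-positive F_IS (no heterozygote deficit) yields s = 0.
    """
    if np.isnan(fis):
        return float("nan")
    if fis <= 0:
        return 0.0
    return float(min(2.0 * fis / (1.0 + fis), 1.0))


def fis_from_selfing(s: float) -> float:
    """Equilibrium inbreeding coefficient F = s/(2-s); inverse of
    :func:`selfing_from_fis` on (0, 1]."""
    return s / (2.0 - s)


def eligible_sites(
    meta: pd.DataFrame,
    assignment,
    min_haplogroups: int = 2,
) -> list[str]:
    """Sites eligible for selfing estimation.

    A site qualifies when every genotyped tissue at the site is grown
    from field-collected seed or is a mature field-grown plant (material
    not yet exposed to viability selection under lab conditions), and at
    least ``min_haplogroups`` distinct haplogroups occur there (a
    monomorphic site carries no information about outcrossing).
    """
    group_of = assignment.group_of
    not_covered = [s for s in meta["sample_id"] if s not in group_of]
    if not_covered:
        raise ValueError(f"assignment does not cover sample {not_covered[0]!r}")
    out = []
    allowed = {FIELD_SEED_GROWN, FIELD_MATURE}
    for site_id, sub in meta.groupby("site_id", sort=True):
        if not sub["tissue_source"].isin(allowed).all():
            continue
        n_groups = len({group_of[s] for s in sub["sample_id"]})
        if n_groups >= min_haplogroups:
            out.append(site_id)
    return out


def site_selfing_with_ci(
    calls: np.ndarray,
    site_id: str = "",
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> SiteMatingEstimate:
    """Point estimate of s for one site with a locus-bootstrap CI.

    Loci are resampled with replacement ``n_boot`` times; replicates in
    which every resampled locus is monomorphic are dropped (and if they
    exceed half the replicates the CI is reported undefined).
    """
    calls = np.asarray(calls)
    fis, comp = site_fis(calls)
    s = selfing_from_fis(fis)
    if comp.empty:
        return SiteMatingEstimate(
            site_id, float("nan"), float("nan"), float("nan"), float("nan"),
            calls.shape[0], 0,
        )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    L = calls.shape[1]
    h_obs = np.zeros(L)
    h_exp = np.zeros(L)
    h_obs[comp["locus"]] = comp["h_obs"]
    h_exp[comp["locus"]] = comp["h_exp"]
    reps = []
    n_undef = 0
    for _ in range(n_boot):
        pick = rng.integers(0, L, size=L)
        se = h_exp[pick].sum()
        if se <= 0:
            n_undef += 1
            continue
        reps.append(selfing_from_fis(1.0 - h_obs[pick].sum() / se))
    if n_undef > n_boot / 2:
        lo = hi = float("nan")
    else:
        a = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(reps, [a, 1.0 - a])
    return SiteMatingEstimate(
        site_id, fis, s, float(lo), float(hi), calls.shape[0], len(comp)
    )


def het_count_distribution(gt: GenotypeTable) -> tuple[np.ndarray, pd.DataFrame]:
    """Heterozygous-locus count per plant plus a quantile summary.

    The summary frame has quantiles (0.5, 0.75, 0.9, 0.95, 0.99) of the
    per-plant count; use :func:`fraction_at_most` for "fraction of
    plants with <= t heterozygous loci" statements.
    """
    counts = (gt.calls == HET).sum(axis=1)
    qs = [0.5, 0.75, 0.9, 0.95, 0.99]
    summary = pd.DataFrame(
        {"quantile": qs, "het_count": np.quantile(counts, qs) if len(counts) else np.nan}
    )
    return counts, summary


def fraction_at_most(counts: np.ndarray, t: int) -> float:
    """Fraction of plants with at most t heterozygous loci."""
    counts = np.asarray(counts)
    if counts.size == 0:
        return float("nan")
    return float((counts <= t).mean())


def site_mating_table(
    gt: GenotypeTable,
    meta: pd.DataFrame,
    assignment,
    min_haplogroups: int = 2,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Selfing estimates for every eligible site.

    Returns one row per eligible site with at least 2 genotyped plants:
    site_id, n_plants, n_loci_used, F_IS, selfing, ci_low, ci_high.
    """
    sites = eligible_sites(meta, assignment, min_haplogroups=min_haplogroups)
    idx_of = {s: i for i, s in enumerate(gt.sample_ids)}
    rng = np.random.default_rng(seed)
    rows = []
    for site_id in sites:
        ids = meta.loc[meta["site_id"] == site_id, "sample_id"]
        idx = [idx_of[s] for s in ids if s in idx_of]
        if len(idx) < 2:
            logger.info("site %s skipped: fewer than 2 genotyped plants", site_id)
            continue
        est = site_selfing_with_ci(
            gt.calls[idx], site_id=site_id, n_boot=n_boot, ci_level=ci_level, seed=rng
        )
        if np.isnan(est.fis):
            logger.info("site %s skipped: no polymorphic locus", site_id)
        rows.append(
            {
                "site_id": est.site_id,
                "n_plants": est.n_plants,
                "n_loci_used": est.n_loci_used,
                "F_IS": est.fis,
                "selfing": est.selfing,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "n_plants", "n_loci_used", "F_IS", "selfing",
            "ci_low", "ci_high",
        ],
    )


def aggregate_selfing(table: pd.DataFrame) -> dict[str, float]:
    """Plant-weighted and site-weighted mean selfing over defined sites."""
    ok = table.dropna(subset=["selfing"])
    if ok.empty:
        return {"plant_weighted": float("nan"), "site_weighted": float("nan")}
    w = ok["n_plants"].to_numpy(float)
    s = ok["selfing"].to_numpy(float)
    return {
        "plant_weighted": float(np.average(s, weights=w)),
        "site_weighted": float(s.mean()),
    }
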