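"""Isolation by distance: great-circle distances, multi-scale distance
binning of pair statistics, linear and exponential curve fits, and
pairwise-site F_ST against log distance.

The per-pair statistics binned here are (a) whether the two plants
belong to the same haplogroup and (b) their mismatch fraction.  Bins
are half-open [low, high) of fixed width (the presets 150, 10 and
0.5 km span continental to within-field scales).  Curve shapes follow
the descriptive fits used for such data: y = m x + b, an exponential
decay y = C exp(-lambda x), and a saturating rise y = K - C
exp(-lambda x).

Site differentiation uses the Weir-Cockerham theta estimator of F_ST
(two populations per site pair, variance components combined across
loci as a ratio of sums, negative estimates retained), regressed on
ln(distance) globally and in sliding windows of consecutive pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import HET, HOM_ALT, MISSING, GenotypeTable

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

QUANTILES = (0.09, 0.25, 0.50, 0.75, 0.91)
QUANTILE_COLS = ("q09", "q25", "q50", "q75", "q91")


@dataclass(frozen=True)
class DistanceBinSpec:
    """Fixed-width half-open distance bins."""

    bin_width_km: float
    max_distance_km: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width_km <= 0:
            raise ValueError("bin_width_km must be positive")


@dataclass
class CurveFit:
    form: Literal["LINEAR", "EXP_DECAY", "EXP_SATURATING"]
    params: dict[str, float]
    rss: float
    converged: bool


@dataclass
class FstDistanceResult:
    pairs: pd.DataFrame  # site_a, site_b, fst, km, ln_km
    slope: float
    intercept: float
    r_value: float
    p_value: float
    window_slopes: pd.DataFrame  # window start distance + slope
    n_excluded_zero_distance: int


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius); vectorised."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pair_geography(meta: pd.DataFrame, gt: GenotypeTable) -> np.ndarray:
    """Great-circle km between every unordered sample pair, in the order
    of ``np.triu_indices(n, 1)`` over ``gt.sample_ids``."""
    pos = meta.set_index("sample_id")
    lat = np.asarray([pos.at[s, "latitude"] for s in gt.sample_ids], dtype=float)
    lon = np.asarray([pos.at[s, "longitude"] for s in gt.sample_ids], dtype=float)
    iu = np.triu_indices(len(lat), k=1)
    return haversine_km(lat[iu[0]], lon[iu[0]], lat[iu[1]], lon[iu[1]])


def bin_pairs(
    distances_km: np.ndarray,
    same_group: np.ndarray | None,
    mismatch_fraction: np.ndarray | None,
    spec: DistanceBinSpec,
) -> pd.DataFrame:
    """Bin pair statistics by distance: floor(d / width) indexes the bin.

    Returns one row per bin up to the furthest occupied bin (or the
    cap), with pair counts, the same-haplogroup proportion, and
    mismatch-fraction quantiles (9th/25th/50th/75th/91st percentiles,
    linear interpolation).  Empty bins carry n_pairs 0 and NaN
    statistics.  Pairs with NaN mismatch fraction count toward n_pairs
    and the same-group proportion but not the quantiles.
    """
    d = np.asarray(distances_km, dtype=float)
    if spec.max_distance_km is not None:
        keep = d < spec.max_distance_km
    else:
        keep = np.ones(len(d), dtype=bool)
    idx = np.floor(d[keep] / spec.bin_width_km).astype(int)
    n_bins = (
        int(np.ceil(spec.max_distance_km / spec.bin_width_km))
        if spec.max_distance_km is not None
        else (int(idx.max()) + 1 if len(idx) else 0)
    )
    rows = []
    sg = np.asarray(same_group)[keep] if same_group is not None else None
    mf = np.asarray(mismatch_fraction, dtype=float)[keep] if mismatch_fraction is not None else None
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        row = {
            "bin_low_km": b * spec.bin_width_km,
            "bin_high_km": (b + 1) * spec.bin_width_km,
            "n_pairs": n,
            "p_same_haplogroup": float(sg[sel].mean()) if (sg is not None and n) else np.nan,
        }
        if mf is not None and n:
            vals = mf[sel]
            vals = vals[~np.isnan(vals)]
            qs = np.quantile(vals, QUANTILES) if len(vals) else [np.nan] * 5
        else:
            qs = [np.nan] * 5
        row.update(dict(zip(QUANTILE_COLS, qs)))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["bin_low_km", "bin_high_km", "n_pairs", "p_same_haplogroup",
                 *QUANTILE_COLS],
    )


def _xyw(
    binned: pd.DataFrame,
    response: str,
    weighting: Literal["none", "by_n_pairs"],
    min_pairs_per_bin: int,
):
    ok = (binned["n_pairs"] >= min_pairs_per_bin) & binned[response].notna()
    x = ((binned["bin_low_km"] + binned["bin_high_km"]) / 2.0)[ok].to_numpy(float)
    y = binned.loc[ok, response].to_numpy(float)
    if weighting == "by_n_pairs":
        w = binned.loc[ok, "n_pairs"].to_numpy(float)
    elif weighting == "none":
        w = np.ones(ok.sum())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return x, y, w


def fit_linear(
    binned: pd.DataFrame,
    response: str = "p_same_haplogroup",
    weighting: Literal["none", "by_n_pairs"] = "by_n_pairs",
    min_pairs_per_bin: int = 5,
) -> CurveFit:
    """Weighted least-squares line y = m x + b on bin midpoints."""
    x, y, w = _xyw(binned, response, weighting, min_pairs_per_bin)
    if len(x) < 2:
        raise ValueError("need at least 2 informative bins")
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid = y - X @ beta
    return CurveFit(
        form="LINEAR",
        params={"m": float(beta[0]), "b": float(beta[1])},
        rss=float(w @ resid**2),
        converged=True,
    )


def fit_exp_decay(
    binned: pd.DataFrame,
    form: Literal["EXP_DECAY", "EXP_SATURATING"] = "EXP_DECAY",
    response: str = "p_same_haplogroup",
    weighting: Literal["none", "by_n_pairs"] = "by_n_pairs",
    min_pairs_per_bin: int = 5,
) -> CurveFit:
    """Nonlinear least squares for y = C exp(-lambda x) or
    y = K - C exp(-lambda x).

    Initialisation: C0 from the first informative bin, lambda0 from a
    log-linear regression of the positive responses, K0 from the last
    bin.  A solver failure or a negative fitted decay rate is reported
    as converged=False rather than raised, mirroring data that simply do
    not follow an exponential.
    """
    x, y, w = _xyw(binned, response, weighting, min_pairs_per_bin)
    need = 4 if form == "EXP_SATURATING" else 3
    if len(x) < need:
        raise ValueError(f"need at least {need} informative bins for {form}")
    sigma = 1.0 / np.sqrt(w)

    # decay-rate start value from a log-linear regression; the sign is kept,
    # so data trending the wrong way drive lambda negative and are reported
    # as non-convergent rather than forced onto the curve
    if form == "EXP_DECAY":
        pos = y > 0
        if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
            lam0 = -np.polyfit(x[pos], np.log(y[pos]), 1)[0]
        else:
            lam0 = 1.0 / max(np.ptp(x), 1.0)
    else:
        # saturating rise: regress the log residual against the plateau
        resid = (y.max() + 0.05 * (np.ptp(y) + 1e-6)) - y
        ok = resid > 0
        if ok.sum() >= 2 and np.ptp(x[ok]) > 0:
            lam0 = -np.polyfit(x[ok], np.log(resid[ok]), 1)[0]
        else:
            lam0 = 1.0 / max(np.ptp(x), 1.0)

    try:
        if form == "EXP_DECAY":
            p0 = [y[0] if abs(y[0]) > 1e-6 else 1e-6, lam0]
            popt, _ = optimize.curve_fit(
                lambda t, C, lam: C * np.exp(-lam * t), x, y,
                p0=p0, sigma=sigma, maxfev=10_000,
            )
            C, lam = popt
            pred = C * np.exp(-lam * x)
            params = {"C": float(C), "lam": float(lam)}
        else:
            p0 = [y.max(), max(y[-1] - y[0], 1e-6), lam0]
            popt, _ = optimize.curve_fit(
                lambda t, K, C, lam: K - C * np.exp(-lam * t), x, y,
                p0=p0, sigma=sigma, maxfev=10_000,
            )
            K, C, lam = popt
            pred = K - C * np.exp(-lam * x)
            params = {"K": float(K), "C": float(C), "lam": float(lam)}
        converged = bool(np.isfinite(list(params.values())).all() and params["lam"] >= 0)
    except (RuntimeError, optimize.OptimizeWarning):
        params = {"C": np.nan, "lam": np.nan} if form == "EXP_DECAY" else {
            "K": np.nan, "C": np.nan, "lam": np.nan}
        pred = np.full_like(y, np.nan)
        converged = False
    rss = float(np.nansum(w * (y - pred) ** 2)) if converged else float("nan")
    return CurveFit(form=form, params=params, rss=rss, converged=converged)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _allele_stats(calls: np.ndarray):
    """Per-locus (n individuals, alt freq, het fraction) over non-missing
    calls; heterozygotes are real genotype calls here, not missing."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    alt = (2 * (calls == HOM_ALT) + (calls == HET)).sum(axis=0)
    het = ((calls == HET) & nonmiss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        h = het / n
    return n, p, h


def weir_cockerham_theta(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Two-population Weir-Cockerham theta (F_ST), combined across loci
    as the ratio of summed variance components a / (a + b + c).

    Loci where either population has fewer than 2 genotyped individuals,
    or where the pooled sample is monomorphic, contribute nothing.
    Negative combined estimates are returned as-is.
    """
    r = 2.0
    n1, p1, h1 = _allele_stats(calls_a)
    n2, p2, h2 = _allele_stats(calls_b)
    ok = (n1 >= 2) & (n2 >= 2)
    n1, p1, h1, n2, p2, h2 = (v[ok] for v in (n1, p1, h1, n2, p2, h2))
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
    poly = (pbar > 0) & (pbar < 1)
    denom = (a + b + c)[poly].sum()
    if not poly.any() or denom == 0:
        return float("nan")
    return float(a[poly].sum() / denom)


def pairwise_site_fst(
    gt: GenotypeTable,
    meta: pd.DataFrame,
    min_plants_per_site: int = 4,
    continent: str | None = None,
) -> pd.DataFrame:
    """Weir-Cockerham theta for every pair of sufficiently sampled sites.

    Sites with fewer than ``min_plants_per_site`` genotyped plants are
    excluded (logged); restrict to one continent with ``continent``.
    Returns site_a, site_b, fst, km, ln_km (NaN ln for coincident sites).
    """
    sub = meta if continent is None else meta[meta["continent"] == continent]
    idx_of = {s: i for i, s in enumerate(gt.sample_ids)}
    site_idx: dict[str, list[int]] = {}
    site_pos: dict[str, tuple[float, float]] = {}
    for site_id, grp in sub.groupby("site_id", sort=True):
        idx = [idx_of[s] for s in grp["sample_id"] if s in idx_of]
        if len(idx) < min_plants_per_site:
            logger.info("site %s excluded from F_ST (%d plants)", site_id, len(idx))
            continue
        site_idx[site_id] = idx
        site_pos[site_id] = (grp["latitude"].iloc[0], grp["longitude"].iloc[0])
    sites = list(site_idx)
    if len(sites) < 2:
        raise ValueError("need at least 2 eligible sites for F_ST")
    rows = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            sa, sb = sites[i], sites[j]
            theta = weir_cockerham_theta(gt.calls[site_idx[sa]], gt.calls[site_idx[sb]])
            km = float(
                haversine_km(*site_pos[sa], *site_pos[sb])
            )
            rows.append(
                {
                    "site_a": sa,
                    "site_b": sb,
                    "fst": theta,
                    "km": km,
                    "ln_km": np.log(km) if km > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["site_a", "site_b", "fst", "km", "ln_km"])


def fst_distance_regression(
    fst_table: pd.DataFrame, window: int = 500
) -> FstDistanceResult:
    """OLS of F_ST on ln(distance) plus sliding-window slopes.

    Pairs at zero distance (no finite ln) or with undefined F_ST are
    excluded and logged.  Windows hold ``window`` consecutive pairs
    ordered by distance, step 1; the final partial window is dropped.
    With fewer pairs than the window only the global regression is
    reported.
    """
    t = fst_table.dropna(subset=["fst"])
    n_zero = int(t["ln_km"].isna().sum())
    if n_zero:
        logger.info("excluding %d site pairs at zero distance", n_zero)
    t = t.dropna(subset=["ln_km"]).sort_values("km").reset_index(drop=True)
    if len(t) < 2:
        raise ValueError("need at least 2 site pairs with defined F_ST and distance")
    x = t["ln_km"].to_numpy(float)
    y = t["fst"].to_numpy(float)
    res = stats.linregress(x, y)
    win_rows = []
    if window >= 2 and len(t) >= window:
        for s in range(len(t) - window + 1):
            xs, ys = x[s : s + window], y[s : s + window]
            if np.ptp(xs) == 0:
                slope = np.nan
            else:
                slope = stats.linregress(xs, ys).slope
            win_rows.append(
                {
                    "start_km": float(t["km"].iloc[s]),
                    "mid_km": float(t["km"].iloc[s : s + window].median()),
                    "slope": float(slope),
                }
            )
    return FstDistanceResult(
        pairs=t,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        p_value=float(res.pvalue),
        window_slopes=pd.DataFrame(win_rows, columns=["start_km", "mid_km", "slope"]),
        n_excluded_zero_distance=n_zero,
    )


def ibd_pair_stats(
    gt: GenotypeTable,
    meta: pd.DataFrame,
    assignment,
    het_as_missing: bool = True,
) -> pd.DataFrame:
    """Per-pair table of distance, same-haplogroup flag, and mismatch
    fraction — the input to multi-scale binning."""
    from .core_data import mismatch_matrix

    km = pair_geography(meta, gt)
    k_mat, n_mat = mismatch_matrix(gt.calls, het_as_missing=het_as_missing)
    iu = np.triu_indices(gt.n_samples, k=1)
    ks, ns = k_mat[iu], n_mat[iu]
    with np.errstate(invalid="ignore"):
        frac = np.where(ns > 0, ks / np.maximum(ns, 1), np.nan)
    group_of = assignment.group_of
    g = np.asarray([group_of[s] for s in gt.sample_ids])
    same = g[iu[0]] == g[iu[1]]
    return pd.DataFrame(
        {"km": km, "same_haplogroup": same, "mismatch_fraction": frac}
    )


def multiscale_binned_ibd(
    pair_stats: pd.DataFrame,
    bin_widths_km=(150.0, 10.0, 0.5),
    max_distance_km: float | None = None,
) -> dict[float, pd.DataFrame]:
    """Binned IBD tables at several bin widths (continental to local)."""
    out = {}
    for w in bin_widths_km:
        out[w] = bin_pairs(
            pair_stats["km"].to_numpy(),
            pair_stats["same_haplogroup"].to_numpy(),
            pair_stats["mismatch_fraction"].to_numpy(),
            DistanceBinSpec(bin_width_km=w, max_distance_km=max_distance_km),
        )
    return out
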