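"""Synthetic genotype + geography generators.

Two layers:

* :func:`generate_equilibrium_site` draws genotypes from a mixed-mating
  (partial-selfing) equilibrium: at each locus a plant is, with
  probability F, an "inbred" draw (homozygous for an allele chosen by the
  local allele frequency) and otherwise a Hardy-Weinberg draw.  This is
  the model under which the inbreeding coefficient F_IS recovers F, and
  hence the selfing rate s = 2F/(1+F).

* :func:`generate_landscape` lays field sites out on a geographic extent
  and produces one of two contrasting spatial scenarios:

  - ``EURASIA``: per-site allele frequencies are a spatially
    autocorrelated perturbation of a shared baseline (distance-decaying
    Gaussian field on the logit scale), so that expected pairwise
    mismatch grows smoothly with distance — isolation by distance.
  - ``NORTH_AMERICA``: a handful of founder haplotypes spread clonally;
    each site is dominated by error-perturbed copies of one founder,
    mimicking a recent colonist whose un-recombined haplotypes blanket a
    continent with little continental-scale structure.

Every generator is deterministic given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core_data import (
    EURASIA,
    FIELD_SEED_GROWN,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NORTH_AMERICA,
    CALL_DTYPE,
    GenotypeTable,
    SnpPanel,
)

#: km per degree of latitude (spherical Earth, mean radius)
KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class SimPanelSpec:
    """Marker-panel simulation spec: ascertained biallelic SNPs with
    intermediate minor allele frequencies (defaults match a panel
    ascertained at MAF 25-30%)."""

    n_markers: int = 139
    maf_low: float = 0.25
    maf_high: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")


@dataclass(frozen=True)
class SimSiteSpec:
    """One simulated field site."""

    site_id: str
    latitude: float = 0.0
    longitude: float = 0.0
    n_plants: int = 20
    inbreeding_F: float = 0.95
    clone_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be positive")
        for v in (self.inbreeding_F, self.clone_fraction):
            if not (0.0 <= v <= 1.0):
                raise ValueError("proportions must be in [0, 1]")


@dataclass(frozen=True)
class LandscapeSpec:
    """A multi-site landscape scenario.

    frequency_gradient_scale_km controls the spatial autocorrelation of
    per-site allele frequencies (EURASIA) and of founder choice
    (NORTH_AMERICA); gradient_sd is the marginal s.d. of the logit-scale
    frequency perturbation.  Plants per site are drawn uniformly on
    [plants_per_site_min, plants_per_site_max].
    """

    scenario: Literal["EURASIA", "NORTH_AMERICA", "CUSTOM"] = "EURASIA"
    n_sites: int = 50
    extent_km: float = 3000.0
    frequency_gradient_scale_km: float = 1000.0
    gradient_sd: float = 1.0
    n_founder_clones: int = 5
    clone_fraction: float = 0.9
    inbreeding_F: float = 0.95
    inbreeding_F_sd: float = 0.02
    plants_per_site_min: int = 5
    plants_per_site_max: int = 40
    error_rate: float = 0.005
    missing_rate: float = 0.02
    origin_lat: float = 45.0
    origin_lon: float = 0.0
    panel: SimPanelSpec = field(default_factory=SimPanelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km <= 0:
            raise ValueError("extent_km must be positive")
        for v in (self.error_rate, self.missing_rate, self.clone_fraction):
            if not (0.0 <= v <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if not (1 <= self.plants_per_site_min <= self.plants_per_site_max):
            raise ValueError("invalid plants_per_site range")


def generate_panel(spec: SimPanelSpec) -> tuple[SnpPanel, np.ndarray]:
    """Generate marker metadata and baseline alt-allele frequencies.

    Frequencies are uniform on [maf_low, maf_high]; the alt allele is the
    minor allele at baseline.  Markers are spread over 5 chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = rng.uniform(spec.maf_low, spec.maf_high, size=spec.n_markers)
    n = spec.n_markers
    chroms = [f"chr{1 + i % 5}" for i in range(n)]
    positions = np.arange(1, n + 1) * 100_000
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n)
    # alt differs from ref
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    panel = SnpPanel(
        pd.DataFrame(
            {
                "marker_id": [f"snp{i + 1:04d}" for i in range(n)],
                "chromosome": chroms,
                "position": positions,
                "ref_allele": ref,
                "alt_allele": alt,
            }
        )
    )
    return panel, freqs


def _equilibrium_calls(
    n_plants: int, freqs: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n_plants, L) call matrix at inbreeding equilibrium.

    Per plant per locus, independently: with probability F an inbred draw
    (HOM_ALT w.p. p else HOM_REF); with probability 1-F a Hardy-Weinberg
    draw (HOM_ALT p^2, HET 2p(1-p), HOM_REF (1-p)^2).
    """
    p = np.asarray(freqs)[None, :]
    shape = (n_plants, p.shape[1])
    inbred = rng.random(shape) < F
    u = rng.random(shape)
    hw = np.where(u < (1 - p) ** 2, HOM_REF, np.where(u < 1 - p**2, HET, HOM_ALT))
    ib = np.where(rng.random(shape) < p, HOM_ALT, HOM_REF)
    return np.where(inbred, ib, hw).astype(CALL_DTYPE)


def generate_equilibrium_site(
    spec: SimSiteSpec, freqs: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Genotypes for one field site at inbreeding equilibrium.

    Returns an (n_plants, len(freqs)) call matrix; ``freqs`` are the
    site's alt-allele frequencies, which must lie strictly in (0, 1).
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return _equilibrium_calls(spec.n_plants, freqs, spec.inbreeding_F, rng)


def apply_genotyping_noise(
    gt: GenotypeTable,
    error_rate: float,
    missing_rate: float,
    seed: int | np.random.Generator = 0,
    het_error: bool = False,
) -> GenotypeTable:
    """Perturb calls with genotyping error and missingness.

    Each homozygous call is flipped to the opposite homozygote with
    probability ``error_rate`` (to a heterozygote instead when
    ``het_error``); afterwards every non-missing call is set missing with
    probability ``missing_rate``.  The error targets homozygotes because
    downstream analyses treat heterozygous calls as missing, so a
    hom->het error would act as extra missingness, not as a mismatch.
    """
    for v in (error_rate, missing_rate):
        if not (0.0 <= v <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    calls = gt.calls.copy()
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    flip = hom & (rng.random(calls.shape) < error_rate)
    if het_error:
        calls[flip] = HET
    else:
        calls[flip] = 2 - calls[flip]  # 0 <-> 2
    drop = (calls != MISSING) & (rng.random(calls.shape) < missing_rate)
    calls[drop] = MISSING
    return GenotypeTable(gt.panel, list(gt.sample_ids), calls)


def _site_coordinates(
    spec: LandscapeSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform site coordinates over a lat/lon rectangle of side extent_km."""
    dlat = spec.extent_km / KM_PER_DEG_LAT
    dlon = spec.extent_km / (KM_PER_DEG_LAT * np.cos(np.radians(spec.origin_lat)))
    lat = spec.origin_lat + rng.uniform(0, dlat, size=spec.n_sites)
    lon = spec.origin_lon + rng.uniform(0, dlon, size=spec.n_sites)
    return lat, lon


def _site_distance_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    from .spatial_ibd import haversine_km

    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def _correlated_site_frequencies(
    baseline: np.ndarray,
    dist_km: np.ndarray,
    scale_km: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site allele frequencies with distance-decaying correlation.

    A Gaussian field with covariance sd^2 * exp(-d/scale) is added to the
    logit of the baseline frequency, independently per marker; the result
    is truncated to (0.02, 0.98).  scale -> 0 degenerates to independent
    site effects (no spatial structure).
    """
    n_sites = dist_km.shape[0]
    L = baseline.shape[0]
    if scale_km > 0:
        cov = sd**2 * np.exp(-dist_km / scale_km)
        # jitter for numerical positive-definiteness
        cov = cov + 1e-9 * np.eye(n_sites)
        chol = np.linalg.cholesky(cov)
        z = chol @ rng.standard_normal((n_sites, L))
    else:
        z = sd * rng.standard_normal((n_sites, L))
    logit = np.log(baseline / (1 - baseline))[None, :] + z
    freqs = 1.0 / (1.0 + np.exp(-logit))
    return np.clip(freqs, 0.02, 0.98)


def generate_landscape(
    spec: LandscapeSpec,
) -> tuple[GenotypeTable, pd.DataFrame, dict]:
    """Generate a full landscape: genotypes, metadata, and ground truth.

    Returns (GenotypeTable, metadata frame, truth record).  The truth
    record carries everything recovery tests need: per-site inbreeding F,
    per-site allele frequencies or founder assignment, per-plant founder
    labels (NORTH_AMERICA), and the gradient scale.
    """
    rng = np.random.default_rng(spec.seed)
    panel, baseline = generate_panel(
        SimPanelSpec(
            n_markers=spec.panel.n_markers,
            maf_low=spec.panel.maf_low,
            maf_high=spec.panel.maf_high,
            seed=int(rng.integers(2**31)),
        )
    )
    lat, lon = _site_coordinates(spec, rng)
    n_plants = rng.integers(
        spec.plants_per_site_min, spec.plants_per_site_max + 1, size=spec.n_sites
    )
    site_F = np.clip(
        rng.normal(spec.inbreeding_F, spec.inbreeding_F_sd, size=spec.n_sites), 0.0, 1.0
    )
    continent = EURASIA if spec.scenario == "EURASIA" else NORTH_AMERICA

    dist = _site_distance_matrix(lat, lon)
    truth: dict = {
        "scenario": spec.scenario,
        "gradient_scale_km": spec.frequency_gradient_scale_km,
        "site_F": site_F.tolist(),
        "baseline_freqs": baseline.tolist(),
    }

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    founder_of_plant: list[int] = []

    if spec.scenario in ("EURASIA", "CUSTOM"):
        site_freqs = _correlated_site_frequencies(
            baseline, dist, spec.frequency_gradient_scale_km, spec.gradient_sd, rng
        )
        truth["site_freqs"] = site_freqs.tolist()
        for s in range(spec.n_sites):
            blocks.append(
                _equilibrium_calls(int(n_plants[s]), site_freqs[s], site_F[s], rng)
            )
    elif spec.scenario == "NORTH_AMERICA":
        founders = np.where(
            rng.random((spec.n_founder_clones, panel.n_markers)) < baseline[None, :],
            HOM_ALT,
            HOM_REF,
        ).astype(CALL_DTYPE)
        # founder origins: random sites; founder choice decays with distance
        origin_sites = rng.choice(spec.n_sites, size=spec.n_founder_clones)
        scale = max(spec.frequency_gradient_scale_km, 1e-9)
        truth["founders"] = founders.tolist()
        site_founder: list[int] = []
        for s in range(spec.n_sites):
            w = np.exp(-dist[s, origin_sites] / scale)
            w = w / w.sum()
            f = int(rng.choice(spec.n_founder_clones, p=w))
            site_founder.append(f)
            n_s = int(n_plants[s])
            n_clone = int(np.round(spec.clone_fraction * n_s))
            clones = np.tile(founders[f], (n_clone, 1))
            wild = _equilibrium_calls(n_s - n_clone, baseline, site_F[s], rng)
            blocks.append(np.vstack([clones, wild]).astype(CALL_DTYPE))
            founder_of_plant.extend([f] * n_clone + [-1] * (n_s - n_clone))
        truth["site_founder"] = site_founder
        truth["founder_of_plant"] = founder_of_plant
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown scenario {spec.scenario!r}")

    for s in range(spec.n_sites):
        for j in range(int(n_plants[s])):
            sid = f"S{s + 1:03d}_P{j + 1:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "latitude": float(lat[s]),
                    "longitude": float(lon[s]),
                    "site_id": f"S{s + 1:03d}",
                    "continent": continent,
                    "tissue_source": FIELD_SEED_GROWN,
                }
            )

    calls = np.vstack(blocks).astype(CALL_DTYPE)
    gt = GenotypeTable(panel, sample_ids, calls)
    gt = apply_genotyping_noise(
        gt, spec.error_rate, spec.missing_rate, seed=rng
    )
    meta = pd.DataFrame(meta_rows)
    return gt, meta, truth
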