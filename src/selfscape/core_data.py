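"""Core domain types, genotype/metadata I/O, QC filters, and the pairwise
mismatch kernel.

Genotype calls are stored as a dense ``int8`` matrix with the codes

==========  ====  =======================================
symbol      code  meaning
==========  ====  =======================================
HOM_REF      0    homozygous for the reference allele
HET          1    heterozygous
HOM_ALT      2    homozygous for the alternate allele
MISSING     -1    no call
==========  ====  =======================================

The TSV dialect mirrors these codes directly (``0``/``1``/``2``/``NA``).
Downstream statistics (clustering distances, mismatch distributions)
treat heterozygous calls as missing by default, because a heterozygous
plant carries both alleles and cannot be placed on either side of a
haplotype comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Call codes
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

CALL_DTYPE = np.int8

# Continent / tissue vocabularies for sample metadata
EURASIA = "EURASIA"
NORTH_AMERICA = "NORTH_AMERICA"
OTHER = "OTHER"
CONTINENTS = (EURASIA, NORTH_AMERICA, OTHER)

FIELD_SEED_GROWN = "FIELD_SEED_GROWN"
FIELD_MATURE = "FIELD_MATURE"
STOCK_CENTER = "STOCK_CENTER"
UNKNOWN = "UNKNOWN"
TISSUE_SOURCES = (FIELD_SEED_GROWN, FIELD_MATURE, STOCK_CENTER, UNKNOWN)

#: tokens accepted as a missing call on input
MISSING_TOKENS = frozenset({"NA", "N", ".", "./.", ".|."})

#: default sample missingness threshold: more than 50 missing of 149 markers
DEFAULT_SAMPLE_MISSING_FRACTION = 50.0 / 149.0

METADATA_COLUMNS = [
    "sample_id",
    "latitude",
    "longitude",
    "site_id",
    "continent",
    "tissue_source",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class SnpPanel:
    """Marker panel metadata: one row per biallelic SNP.

    ``frame`` columns: marker_id, chromosome, position (1-based bp),
    ref_allele, alt_allele.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position", "ref_allele", "alt_allele"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"panel missing columns: {sorted(missing)}")
        ids = self.frame["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate marker id: {dup!r}")
        if (self.frame["position"] < 1).any():
            raise ValidationError("marker positions must be >= 1")
        same = self.frame["ref_allele"] == self.frame["alt_allele"]
        if same.any():
            raise ValidationError(
                f"ref == alt for marker {self.frame.loc[same, 'marker_id'].iloc[0]!r}"
            )

    @property
    def marker_ids(self) -> list[str]:
        return self.frame["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @staticmethod
    def minimal(marker_ids: Sequence[str]) -> "SnpPanel":
        """Placeholder panel for inputs (plain TSV) that carry no marker
        metadata; positions are column order, alleles are nominal A/T."""
        n = len(marker_ids)
        return SnpPanel(
            pd.DataFrame(
                {
                    "marker_id": list(marker_ids),
                    "chromosome": ["un"] * n,
                    "position": np.arange(1, n + 1),
                    "ref_allele": ["A"] * n,
                    "alt_allele": ["T"] * n,
                }
            )
        )


@dataclass
class GenotypeTable:
    """Samples x markers call matrix plus its marker panel."""

    panel: SnpPanel
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=CALL_DTYPE)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            for s in self.sample_ids:
                if s in seen:
                    raise ValidationError(f"duplicate sample id: {s!r}")
                seen.add(s)
        if self.calls.shape != (len(self.sample_ids), self.panel.n_markers):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {self.panel.n_markers})"
            )
        valid = np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            bad = self.calls[~valid][0]
            raise ValidationError(f"invalid call code {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.panel.n_markers

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def missing_fraction_per_marker(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.calls == MISSING).mean(axis=0)

    def het_fraction_per_marker(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.calls == HET).mean(axis=0)

    def subset_samples(self, keep: np.ndarray | Sequence[int]) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            panel=self.panel,
            sample_ids=[self.sample_ids[i] for i in keep],
            calls=self.calls[keep].copy(),
        )

    def subset_samples_by_id(self, ids: Iterable[str]) -> "GenotypeTable":
        wanted = set(ids)
        idx = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        return self.subset_samples(idx)

    def subset_markers(self, keep: np.ndarray | Sequence[int]) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            panel=SnpPanel(self.panel.frame.iloc[keep].reset_index(drop=True)),
            sample_ids=list(self.sample_ids),
            calls=self.calls[:, keep].copy(),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.panel.marker_ids == other.panel.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class PairMismatch:
    """Mismatch count between two haplotypes over both-informative markers.

    k: markers where the informative calls differ; n: markers informative
    in both haplotypes.  The fraction is undefined (NaN, ``defined`` False)
    when no marker is comparable.
    """

    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValidationError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n > 0 else float("nan")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, fmt: str = "tsv") -> GenotypeTable:
    """Read a genotype table from TSV or VCF.

    TSV dialect: header row of marker ids, first column the sample id,
    calls encoded 0 / 1 / 2 / NA.  VCF: biallelic SNP records only;
    multi-allelic records are dropped with a logged warning count
    (use :func:`read_vcf` to retrieve the count programmatically).
    """
    if fmt == "tsv":
        return _read_tsv(Path(path))
    if fmt == "vcf":
        table, n_rejected = read_vcf(path)
        if n_rejected:
            logger.warning("dropped %d non-biallelic VCF records", n_rejected)
        return table
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_tsv(path: Path) -> GenotypeTable:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeParseError(f"{path}: empty file")
        cols = header.split("\t")
        marker_ids = cols[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:]):
                if tok in MISSING_TOKENS or tok == "":
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: bad call {tok!r} for marker {marker_ids[j]!r}"
                    )
            rows.append(row)
    calls = (
        np.asarray(rows, dtype=CALL_DTYPE)
        if rows
        else np.empty((0, len(marker_ids)), dtype=CALL_DTYPE)
    )
    return GenotypeTable(SnpPanel.minimal(marker_ids), sample_ids, calls)


def read_vcf(path: str | Path) -> tuple[GenotypeTable, int]:
    """Read genotypes from a VCF (4.x, GT field only).

    Returns the table and the number of records rejected for not being
    biallelic SNPs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample id in VCF header")
    rows = []
    panel_rows = []
    n_rejected = 0
    # with gts012=True cyvcf2 codes gt_types 0=hom-ref 1=het 2=hom-alt 3=missing
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_rejected += 1
            continue
        g = np.asarray(var.gt_types, dtype=CALL_DTYPE)
        g[g == 3] = MISSING
        rows.append(g)
        panel_rows.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0])
        )
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(sample_ids), 0), dtype=CALL_DTYPE)
    )
    panel = SnpPanel(
        pd.DataFrame(
            panel_rows,
            columns=["marker_id", "chromosome", "position", "ref_allele", "alt_allele"],
        )
        if panel_rows
        else SnpPanel.minimal([]).frame
    )
    return GenotypeTable(panel, sample_ids, calls), n_rejected


def write_genotypes(gt: GenotypeTable, path: str | Path) -> None:
    """Write the TSV dialect (0/1/2/NA) read back by :func:`read_genotypes`."""
    enc = {HOM_REF: "0", HET: "1", HOM_ALT: "2", MISSING: "NA"}
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(gt.panel.marker_ids) + "\n")
        for i, sid in enumerate(gt.sample_ids):
            fh.write(sid + "\t" + "\t".join(enc[int(c)] for c in gt.calls[i]) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
    lat, lon = meta["latitude"], meta["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValidationError("latitude outside [-90, 90]")
    if ((lon <= -180) | (lon > 180)).any():
        raise ValidationError("longitude outside (-180, 180]")
    bad = ~meta["continent"].isin(CONTINENTS)
    if bad.any():
        raise ValidationError(f"unknown continent {meta.loc[bad, 'continent'].iloc[0]!r}")
    bad = ~meta["tissue_source"].isin(TISSUE_SOURCES)
    if bad.any():
        raise ValidationError(
            f"unknown tissue source {meta.loc[bad, 'tissue_source'].iloc[0]!r}"
        )
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# Data-cleaning filters
# ---------------------------------------------------------------------------

def filter_samples_by_missingness(
    gt: GenotypeTable,
    max_missing_fraction: float = DEFAULT_SAMPLE_MISSING_FRACTION,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop samples whose missing-call fraction exceeds the threshold.

    The default corresponds to the rule "more than 50 missing calls out of
    149 markers", stored as a fraction so it scales to other panel sizes.
    Returns the filtered table and a removal report (sample_id,
    missing_fraction, reason).
    """
    if not (0.0 <= max_missing_fraction <= 1.0):
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = gt.missing_fraction_per_sample()
    removed = frac > max_missing_fraction
    report = pd.DataFrame(
        {
            "sample_id": [s for s, r in zip(gt.sample_ids, removed) if r],
            "missing_fraction": frac[removed],
            "reason": "excess_missing",
        }
    )
    if removed.all():
        logger.warning("sample missingness filter removed every sample")
    return gt.subset_samples(~removed), report


def filter_markers(
    gt: GenotypeTable,
    max_missing_fraction: float = 0.25,
    max_het_fraction: float = 0.25,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop markers with excess missing OR excess heterozygous calls.

    The two criteria are applied separately (a marker failing either is
    removed); both default to a quarter of the sample, the usual symptom
    threshold for a poorly performing genotyping assay.
    """
    for v in (max_missing_fraction, max_het_fraction):
        if not (0.0 <= v <= 1.0):
            raise ValueError("thresholds must be in [0, 1]")
    miss = gt.missing_fraction_per_marker()
    het = gt.het_fraction_per_marker()
    bad_miss = miss > max_missing_fraction
    bad_het = het > max_het_fraction
    removed = bad_miss | bad_het
    reasons = []
    for i in np.flatnonzero(removed):
        r = []
        if bad_miss[i]:
            r.append("excess_missing")
        if bad_het[i]:
            r.append("excess_het")
        reasons.append("+".join(r))
    report = pd.DataFrame(
        {
            "marker_id": [gt.panel.marker_ids[i] for i in np.flatnonzero(removed)],
            "missing_fraction": miss[removed],
            "het_fraction": het[removed],
            "reason": reasons,
        }
    )
    return gt.subset_markers(~removed), report


def remove_blacklisted_haplogroups(
    gt: GenotypeTable,
    assignment,
    blacklist_sample_ids: Iterable[str],
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Remove every sample whose haplogroup contains a blacklisted sample.

    Used to strip haplogroups anchored on common lab strains, which at
    broad geographic distributions indicate contamination rather than
    natural spread.  Blacklist ids absent from the data are logged, not
    fatal.  ``assignment`` must cover every sample in ``gt``.
    """
    group_of = assignment.group_of
    not_covered = [s for s in gt.sample_ids if s not in group_of]
    if not_covered:
        raise ValidationError(
            f"haplogroup assignment does not cover sample {not_covered[0]!r}"
        )
    blacklist = set(blacklist_sample_ids)
    present = blacklist & set(gt.sample_ids)
    for absent in sorted(blacklist - present):
        logger.warning("blacklist id %r not present in genotype table", absent)
    bad_groups = {group_of[s] for s in present}
    removed_mask = np.array([group_of[s] in bad_groups for s in gt.sample_ids])
    report = pd.DataFrame(
        {
            "sample_id": [s for s, r in zip(gt.sample_ids, removed_mask) if r],
            "haplogroup": [
                group_of[s] for s, r in zip(gt.sample_ids, removed_mask) if r
            ],
            "reason": "blacklisted_haplogroup",
        }
    )
    return gt.subset_samples(~removed_mask), report


# ---------------------------------------------------------------------------
# Pairwise mismatch kernel
# ---------------------------------------------------------------------------

def _informative(calls: np.ndarray, het_as_missing: bool) -> np.ndarray:
    """Boolean mask of calls usable in a haplotype comparison."""
    mask = calls != MISSING
    if het_as_missing:
        mask &= calls != HET
    return mask


def pairwise_mismatch(
    h1: np.ndarray, h2: np.ndarray, het_as_missing: bool = True
) -> PairMismatch:
    """Mismatch count between two call vectors.

    Positions where either call is missing (or heterozygous under the
    default) are not compared.  A heterozygous call compared against a
    homozygote never counts as a mismatch under the default because it is
    excluded from n.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape:
        raise ValueError(f"length mismatch: {h1.shape} vs {h2.shape}")
    both = _informative(h1, het_as_missing) & _informative(h2, het_as_missing)
    n = int(both.sum())
    k = int((h1[both] != h2[both]).sum())
    return PairMismatch(k=k, n=n)


def mismatch_matrix(
    calls: np.ndarray, het_as_missing: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (K, N) mismatch-count and comparable-count matrices.

    Equivalent to calling :func:`pairwise_mismatch` on every pair, but
    computed with three matrix products over the informative-call masks.
    """
    calls = np.asarray(calls)
    m = _informative(calls, het_as_missing).astype(np.float64)
    if het_as_missing:
        a = (calls == HOM_ALT).astype(np.float64)
    else:
        # treat HET as its own state: mismatch iff states differ; encode via
        # one-hot comparison over the three informative states
        n_mat = m @ m.T
        k_mat = np.zeros_like(n_mat)
        for state in (HOM_REF, HET, HOM_ALT):
            s = ((calls == state) & (m > 0)).astype(np.float64)
            k_mat += s @ (m - s).T
        return np.rint(k_mat).astype(np.int64), np.rint(n_mat).astype(np.int64)
    am = a * m
    n_mat = m @ m.T
    # a_i xor a_j over both-informative positions
    k_mat = am @ m.T + m @ am.T - 2.0 * (am @ am.T)
    return np.rint(k_mat).astype(np.int64), np.rint(n_mat).astype(np.int64)
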