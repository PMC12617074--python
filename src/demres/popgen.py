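"""Windowed population-genetic statistics from diploid biallelic genotypes.

Implements the within- and between-population summaries used to
characterise genetic diversity and differentiation:

* per-site nucleotide diversity pi = a*b / C(n,2) for allele counts (a, b),
  averaged over 10 kb windows;
* Weir & Cockerham's (1984) theta estimator of FST from the among-/within-
  population variance components, aggregated genome-wide as a ratio of
  sums;
* absolute divergence dxy = pA(1-pB) + pB(1-pA) per site, averaged over
  non-overlapping 50 kb windows;
* a minor-allele-frequency filter (default 0.02) applied before all of the
  above;
* great-circle distance between sampling sites, the geographic covariate of
  the downstream adjustment models.

Window coordinates are 0-based half-open internally; VCF positions
(1-based) are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "maf_filter",
    "site_pi",
    "pop_site_pi",
    "window_average",
    "wc_fst",
    "dxy",
    "great_circle_km",
    "pairwise_summary",
]

MISSING = -1
EARTH_RADIUS_KM = 6371.0


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes: sites x individuals alt-allele counts.

    ``genotypes`` holds values in {0, 1, 2} with -1 for missing;
    ``pops`` assigns each individual (column) to a population label.
    """

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    pops: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pops = np.asarray(self.pops, dtype=object)
        n_sites, n_ind = self.genotypes.shape
        if len(self.positions) != n_sites:
            raise ValueError("positions length must match genotype rows")
        if len(self.samples) != n_ind or len(self.pops) != n_ind:
            raise ValueError("samples/pops length must match genotype columns")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be in {0,1,2} or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    def pop_columns(self, pop: str) -> np.ndarray:
        cols = np.flatnonzero(self.pops == pop)
        if len(cols) == 0:
            raise ValueError(f"no individuals assigned to population {pop!r}")
        return cols

    def allele_counts(self, cols: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt count, total observed chromosomes) per site over columns."""
        g = self.genotypes if cols is None else self.genotypes[:, cols]
        obs = g != MISSING
        alt = np.where(obs, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * obs.sum(axis=1).astype(np.int64)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(self, positions=self.positions[mask], genotypes=self.genotypes[mask])


def read_vcf(path, pop_of_sample: dict[str, str]) -> GenotypeMatrix:
    """Load biallelic SNPs from a (single-chromosome) VCF via cyvcf2.

    Sites that are not biallelic SNPs are skipped.  ``pop_of_sample`` maps
    VCF sample names to population labels; samples absent from the mapping
    raise an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_of_sample]
    if missing:
        raise ValueError(f"samples without population assignment: {missing[:5]}")
    positions, rows = [], []
    chrom = None
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError("multi-chromosome VCFs are not supported; split by chromosome")
        positions.append(v.POS)
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0,1,2 = #alt; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no biallelic SNPs found")
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        genotypes=np.vstack(rows),
        samples=samples,
        pops=np.asarray([pop_of_sample[s] for s in samples], dtype=object),
    )


def maf_filter(G: GenotypeMatrix, threshold: float = 0.02) -> GenotypeMatrix:
    """Keep sites with minor-allele frequency >= ``threshold``.

    The frequency is computed from non-missing chromosomes pooled across
    all individuals; monomorphic sites (MAF 0) are always removed.  The
    filter is idempotent.
    """
    alt, n = G.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (n > 0) & (maf >= threshold)
    return G.subset_sites(keep)


def site_pi(a: int, b: int) -> float:
    """Per-site nucleotide diversity for allele counts (a, b): a*b/C(n,2)."""
    n = a + b
    if n < 2:
        return float("nan")
    return a * b / (n * (n - 1) / 2.0)


def pop_site_pi(G: GenotypeMatrix, pop: str) -> np.ndarray:
    """Vectorised per-site pi within one population (NaN where n < 2)."""
    alt, n = G.allele_counts(G.pop_columns(pop))
    ref = n - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, alt * ref / (n * (n - 1) / 2.0), np.nan)
    return pi


def window_average(
    positions: np.ndarray,
    values: np.ndarray,
    window_size: int,
    chrom: str = "chr1",
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Mean of per-site values in non-overlapping half-open windows.

    Windows tile the chromosome from 0 as [k*w, (k+1)*w); ``positions`` are
    0-based here (converted from VCF on read).  The value is the mean over
    *variant sites* in the window (NaN when empty); ``n_sites`` counts the
    sites with a non-missing value.
    """
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    span = chrom_length if chrom_length is not None else (
        int(positions.max()) + 1 if len(positions) else window_size
    )
    n_win = max(1, math.ceil(span / window_size))
    win = positions // window_size
    rows = []
    for k in range(n_win):
        in_win = values[(win == k) & ~np.isnan(values)]
        rows.append(
            {
                "chrom": chrom,
                "start": k * window_size,
                "end": min((k + 1) * window_size, span) if chrom_length else (k + 1) * window_size,
                "value": float(in_win.mean()) if len(in_win) else float("nan"),
                "n_sites": int(len(in_win)),
            }
        )
    return pd.DataFrame(rows)


def _pop_freq_het(G: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n diploids observed, alt frequency, observed het proportion)."""
    g = G.genotypes[:, G.pop_columns(pop)]
    obs = g != MISSING
    n = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=1) / (2.0 * n)
        h = np.where(obs, g == 1, False).sum(axis=1) / n
    return n, p, h


def wc_fst(G: GenotypeMatrix, popA: str, popB: str) -> tuple[pd.DataFrame, float]:
    """Weir & Cockerham (1984) theta for two populations.

    Per site, the among-population (a), among-individual (b) and
    within-individual (c) variance components are computed from the two
    samples' sizes, allele frequencies and observed heterozygosities.
    Sites with fewer than two observed diploids in either population, or
    monomorphic across both, are excluded.  The genome-wide estimate is the
    ratio of sums ``theta = sum(a) / sum(a+b+c)``; per-site ratios are also
    reported (they can be negative).
    """
    n1, p1, h1 = _pop_freq_het(G, popA)
    n2, p2, h2 = _pop_freq_het(G, popB)
    r = 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        usable &= (pbar > 0) & (pbar < 1)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        theta_site = np.where(usable & ((a + b + c) != 0), a / (a + b + c), np.nan)
    per_site = pd.DataFrame(
        {
            "pos": G.positions,
            "a": np.where(usable, a, np.nan),
            "b": np.where(usable, b, np.nan),
            "c": np.where(usable, c, np.nan),
            "theta_site": theta_site,
            "used": usable,
        }
    )
    if not usable.any():
        return per_site, float("nan")
    denom = (a + b + c)[usable].sum()
    theta = float(a[usable].sum() / denom) if denom != 0 else float("nan")
    return per_site, theta


def dxy(
    G: GenotypeMatrix, popA: str, popB: str, window_size: int = 50_000,
    chrom_length: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Absolute divergence pA(1-pB) + pB(1-pA) per site, 50 kb windows.

    Returns the per-site values (NaN where a frequency is not computable)
    and their window means over variant sites.
    """
    n1, p1, _ = _pop_freq_het(G, popA)
    n2, p2, _ = _pop_freq_het(G, popB)
    with np.errstate(invalid="ignore"):
        d = np.where((n1 >= 1) & (n2 >= 1), p1 * (1 - p2) + p2 * (1 - p1), np.nan)
    windows = window_average(
        G.positions - 1, d, window_size, chrom=G.chrom, chrom_length=chrom_length
    )
    return d, windows


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of range [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 360.0:
            raise ValueError(f"longitude {lon} out of range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_summary(
    G: GenotypeMatrix,
    coords: pd.DataFrame,
    maf: float = 0.02,
    dxy_window: int = 50_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """FST, mean dxy and great-circle distance for every population pair.

    ``coords`` must have one row per population with columns population,
    latitude, longitude.
    """
    G = maf_filter(G, maf)
    coords = coords.set_index("population")
    pops = sorted(set(G.pops))
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            _, theta = wc_fst(G, a, b)
            d_site, _ = dxy(G, a, b, window_size=dxy_window, chrom_length=chrom_length)
            rows.append(
                {
                    "pop1": a,
                    "pop2": b,
                    "fst": theta,
                    "dxy": float(np.nanmean(d_site)),
                    "distance_km": great_circle_km(
                        coords.at[a, "latitude"], coords.at[a, "longitude"],
                        coords.at[b, "latitude"], coords.at[b, "longitude"],
                    ),
                }
            )
    return pd.DataFrame(rows)
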