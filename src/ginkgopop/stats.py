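"""Diversity and differentiation statistics.

Estimators follow the standard population-genetic definitions on hard
genotype calls:

* nucleotide diversity  pi = (1/L) sum_s [n_s/(n_s-1)] 2 p_s (1-p_s)
  (unbiased per-site correction; equals the mean pairwise difference count
  per site),
* Watterson's theta     theta_W = S / (a_{n-1} L),  a_m = sum_{i<=m} 1/i,
* expected heterozygosity  H_E = mean_s 2 p_s (1-p_s),
* Hudson's F_ST as a ratio of averages across sites,
* identity-by-state distance  d(i,j) = sum_s |g_i - g_j| / (2 m_pair)
  over pairwise-complete sites (PLINK's ``--distance 1-ibs``).

Missing data: IBS uses pairwise-complete sites; the joint SFS drops sites
with any missing call in the involved populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .sfs import SiteFrequencySpectrum

__all__ = [
    "DiversitySummary",
    "DistanceMatrix",
    "IBS_CUTOFFS",
    "IBS_CATEGORIES",
    "harmonic_number",
    "nucleotide_diversity",
    "watterson_theta",
    "expected_heterozygosity",
    "pairwise_fst",
    "joint_sfs",
    "ibs_distance_matrix",
    "classify_pairs",
    "diversity_summary",
]

#: IBS dispersal-classification cutoffs and the bracket convention:
#: [0, 0.03) near-identical, [0.03, 0.07) early-introduction,
#: [0.07, 0.09] intermediate, (0.09, 1] deep-divergence.
IBS_CUTOFFS = (0.03, 0.07, 0.09)
IBS_CATEGORIES = (
    "near_identical",
    "early_introduction",
    "intermediate",
    "deep_divergence",
)


def harmonic_number(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (the Watterson denominator)."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


@dataclass
class DiversitySummary:
    """Per-population diversity table (Table-1 style reporting)."""

    table: pd.DataFrame  # columns: lineage, n_samples, n_snps, pi, pi_sd, thetaw, thetaw_sd


@dataclass
class DistanceMatrix:
    """Symmetric pairwise IBS distance matrix with per-pair site counts."""

    samples: list[str]
    values: np.ndarray  # (n, n) in [0, 1]; NaN where undefined
    n_sites_used: np.ndarray  # (n, n) pairwise-complete site counts

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.samples):
            raise ValueError("distance matrix must be square over samples")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("IBS distances must lie in [0, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])


# ---------------------------------------------------------------------------


def _freqs(G: GenotypeMatrix, pop: str | None):
    alt, n = G.allele_counts(pop)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def nucleotide_diversity(
    G: GenotypeMatrix, pop: str | None = None, total_length_bp: float | None = None
) -> float:
    """Average number of pairwise nucleotide differences per site.

    ``total_length_bp`` defaults to the summed chromosome lengths carrying
    the sites (monomorphic positions contribute zero but divide the sum).
    """
    if total_length_bp is None:
        total_length_bp = sum(G.chrom_lengths.get(c, 0) for c in dict.fromkeys(G.chroms))
    if not total_length_bp or total_length_bp <= 0:
        raise ValueError("total_length_bp must be > 0")
    p, n = _freqs(G, pop)
    usable = n >= 2
    p, n = p[usable], n[usable]
    per_site = n / (n - 1) * 2.0 * p * (1.0 - p)
    return float(per_site.sum() / total_length_bp)


def watterson_theta(n_segregating: int, n_haploids: int, length_bp: float) -> float:
    """theta_W = S / (a_{n-1} L) per base pair."""
    if n_haploids < 2:
        raise ValueError("Watterson's estimator needs n >= 2 haploids")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if n_segregating == 0:
        return 0.0
    return float(n_segregating / (harmonic_number(n_haploids - 1) * length_bp))


def expected_heterozygosity(
    G: GenotypeMatrix, pop: str | None = None, sites: np.ndarray | None = None
) -> float:
    """Mean over usable sites of 2 p (1-p); NaN when no site is usable."""
    p, n = _freqs(G, pop)
    if sites is not None:
        p, n = p[sites], n[sites]
    usable = n >= 2
    if not usable.any():
        return float("nan")
    p = p[usable]
    return float(np.mean(2.0 * p * (1.0 - p)))


def pairwise_fst(
    G: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    sites: np.ndarray | None = None,
    estimator: str = "hudson",
) -> float:
    """F_ST between two populations, ratio-of-averages across sites.

    Hudson's estimator (default):
        N_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D_s = p1(1-p2) + p2(1-p1),   F_ST = sum N_s / sum D_s.
    ``estimator="wc"`` gives the Weir-Cockerham two-population variant on
    haploid allele counts.  Negative values are reported as computed.
    """
    alt1, n1 = G.allele_counts(pop_a)
    alt2, n2 = G.allele_counts(pop_b)
    if sites is not None:
        alt1, n1, alt2, n2 = alt1[sites], n1[sites], alt2[sites], n2[sites]
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("no site with >= 2 haploid calls in both populations")
    alt1, n1, alt2, n2 = alt1[ok], n1[ok], alt2[ok], n2[ok]
    p1, p2 = alt1 / n1, alt2 / n2
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "wc":
        # Weir & Cockerham (1984) theta-hat on haploid samples, two demes
        r = 2.0
        nbar = (n1 + n2) / r
        csq = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / (r - 1) / nbar**2
        nc = nbar * (1 - csq / r)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = nbar / nc * (ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * ssq)
        num, den = a, a + b
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    dsum = den.sum()
    if dsum == 0:
        return float("nan")
    return float(num.sum() / dsum)


def joint_sfs(
    G: GenotypeMatrix, pops: list[str], folded: bool = False
) -> SiteFrequencySpectrum:
    """Counts of sites on the per-population alternate-allele-count lattice.

    Sites with any missing call in the involved populations are excluded;
    folding merges each cell with its complement onto the global minor
    allele.
    """
    counts = []
    ns = []
    complete = np.ones(G.n_sites, dtype=bool)
    for pop in pops:
        idx = G.sample_indices(pop)
        g = G.genotypes[idx]
        complete &= ~(g == MISSING).any(axis=0)
        counts.append(np.where(g == MISSING, 0, g).sum(axis=0))
        ns.append(2 * len(idx))
    shape = tuple(n + 1 for n in ns)
    data = np.zeros(shape)
    stacked = np.stack([c[complete] for c in counts])
    np.add.at(data, tuple(stacked), 1.0)
    # raw counts keep every observed cell, including sample-fixed ALT
    # sites (masked downstream on normalization); the all-REF corner is
    # not a variant and never carries mass
    data[(0,) * data.ndim] = 0.0
    spec = SiteFrequencySpectrum(tuple(pops), tuple(ns), data, folded=False)
    return spec.fold() if folded else spec


def ibs_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distances (PLINK ``1-ibs``).

    d(i,j) = sum_s |g_i - g_j| / (2 m_pair) over the m_pair sites where
    both calls are present; NaN when a pair shares no complete site.
    """
    g = G.genotypes.astype(np.float64)
    present = g != MISSING
    gz = np.where(present, g, 0.0)
    n = G.n_samples
    d = np.zeros((n, n))
    m = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        both = present[i] & present[j]
        mp = int(both.sum())
        m[i, j] = m[j, i] = mp
        if mp == 0:
            d[i, j] = d[j, i] = np.nan
            continue
        diff = np.abs(gz[i, both] - gz[j, both]).sum()
        d[i, j] = d[j, i] = diff / (2.0 * mp)
    np.fill_diagonal(m, int(present.all(axis=0).sum()))
    return DistanceMatrix(list(G.samples), d, m)


def classify_pairs(
    D: DistanceMatrix, cutoffs: tuple[float, float, float] = IBS_CUTOFFS
) -> pd.DataFrame:
    """Dispersal classification of sample pairs by IBS distance.

    Bracket convention: [0, c1) near-identical, [c1, c2) early-introduction,
    [c2, c3] intermediate, (c3, 1] deep-divergence.
    """
    c1, c2, c3 = cutoffs
    if not (c1 < c2 < c3):
        raise ValueError("cutoffs must be strictly increasing")
    rows = []
    for i, j in itertools.combinations(range(len(D.samples)), 2):
        v = D.values[i, j]
        if np.isnan(v):
            cat = "undefined"
        elif v < c1:
            cat = IBS_CATEGORIES[0]
        elif v < c2:
            cat = IBS_CATEGORIES[1]
        elif v <= c3:
            cat = IBS_CATEGORIES[2]
        else:
            cat = IBS_CATEGORIES[3]
        rows.append((D.samples[i], D.samples[j], v, cat))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "ibs_distance", "category"])


def diversity_summary(
    G: GenotypeMatrix, window_bp: int = 100_000, pops: list[str] | None = None
) -> DiversitySummary:
    """Per-population pi and theta_W with SDs across ``window_bp`` windows."""
    if pops is None:
        pops = G.populations
    rows = []
    for pop in pops:
        idx = G.sample_indices(pop)
        n_hap = 2 * len(idx)
        p, n = _freqs(G, pop)
        seg = (p > 0) & (p < 1) & (n >= 2)
        pis, thetas = [], []
        for chrom in dict.fromkeys(G.chroms):
            on = G.chroms == chrom
            length = G.chrom_lengths.get(chrom, int(G.positions[on].max()))
            pos0 = G.positions[on] - 1
            for start in range(0, max(length, 1), window_bp):
                w = on.copy()
                w[on] = (pos0 >= start) & (pos0 < start + window_bp)
                wlen = min(window_bp, length - start)
                if wlen <= 0:
                    continue
                usable = w & (n >= 2)
                per_site = (
                    n[usable] / (n[usable] - 1) * 2.0 * p[usable] * (1.0 - p[usable])
                )
                pis.append(per_site.sum() / wlen)
                thetas.append(
                    watterson_theta(int((seg & w).sum()), n_hap, wlen)
                    if n_hap >= 2
                    else np.nan
                )
        pis_a, thetas_a = np.array(pis), np.array(thetas)
        rows.append(
            dict(
                lineage=pop,
                n_samples=len(idx),
                n_snps=int(seg.sum()),
                pi=float(np.mean(pis_a)) if pis_a.size else np.nan,
                pi_sd=float(np.std(pis_a, ddof=1)) if pis_a.size > 1 else np.nan,
                thetaw=float(np.mean(thetas_a)) if thetas_a.size else np.nan,
                thetaw_sd=float(np.std(thetas_a, ddof=1)) if thetas_a.size > 1 else np.nan,
            )
        )
    return DiversitySummary(pd.DataFrame(rows))
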