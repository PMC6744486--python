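"""Two-pronged selection scan.

1. Windowed summary statistics: expected heterozygosity of a focal group
   and its F_ST against a contrast group in non-overlapping windows
   (0-based half-open), Z-score-transformed genome-wide; windows with
   strongly elevated Z(F_ST) *and* strongly depleted Z(H_E) are called
   selected (joint-tail rule, 1% normal tails by default).

2. A SweepFinder/SweeD-style composite likelihood ratio (CLR) scan: at
   each grid position the folded site spectra near the point are modeled
   as a sweep-distorted version of the genome-wide background spectrum.
   A lineage at distance d from the sweep escapes with probability
   1 - exp(-alpha d); with k of n lineages escaping, the site's allele
   configuration is the background projected onto k+1 lineages with one
   uniformly chosen lineage replicated n-k times (the hitchhiking class),
   conditioned on polymorphism.  CLR(x) = 2 [max_alpha ln L(alpha) -
   ln L(background)], maximized over a log-spaced alpha grid that always
   includes the background-equivalent limit, so CLR >= 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .genotypes import GenotypeMatrix
from .sfs import SiteFrequencySpectrum

__all__ = [
    "WindowTable",
    "SweepScanResult",
    "window_stats",
    "call_selected_windows",
    "background_spectrum",
    "clr_scan",
    "DEFAULT_ALPHA_GRID",
]

#: 21 log-spaced sweep intensities (alpha per bp), bounded and deterministic
DEFAULT_ALPHA_GRID = np.logspace(-5, 2, 21)

#: 1% normal-tail thresholds for the joint selection rule
Z_FST_MIN_DEFAULT = 2.326
Z_HE_MAX_DEFAULT = -2.326


@dataclass
class WindowTable:
    """Per-window statistics; ``start``/``end`` are 0-based half-open."""

    table: pd.DataFrame  # chrom, start, end, n_snps, he, fst, z_he, z_fst, selected

    def restandardize(self) -> "WindowTable":
        """Recompute Z columns over the currently non-missing rows."""
        df = self.table.copy()
        for col, zcol in (("he", "z_he"), ("fst", "z_fst")):
            v = df[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            z = np.full_like(v, np.nan)
            if ok.sum() >= 2 and np.nanstd(v[ok]) > 0:
                z[ok] = (v[ok] - v[ok].mean()) / v[ok].std()
            df[zcol] = z
        return WindowTable(df)


@dataclass
class SweepScanResult:
    positions: np.ndarray  # grid positions (bp, 1-based coordinates)
    clr: np.ndarray  # >= 0
    alpha_hat: np.ndarray  # argmax intensity; 0 where CLR == 0
    background: SiteFrequencySpectrum


def window_stats(
    G: GenotypeMatrix,
    focal_pop: str,
    other_pop: str,
    window_bp: int = 100_000,
    min_snps: int = 10,
) -> WindowTable:
    """H_E (focal) and F_ST (focal vs other) in non-overlapping windows.

    Windows tile each chromosome as [0, w), [w, 2w), ... in 0-based
    coordinates (1-based positions are shifted down by one).  Windows with
    fewer than ``min_snps`` SNPs get NaN statistics and are excluded from
    the genome-wide Z-transformation.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if G.n_sites == 0:
        raise ValueError("empty genotype matrix")
    # per-site counts computed once; windows then slice into them
    alt1, n1 = G.allele_counts(focal_pop)
    alt2, n2 = G.allele_counts(other_pop)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, alt1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(ok, alt2 / np.maximum(n2, 1), np.nan)
        he_site = 2.0 * p1 * (1.0 - p1)
        fst_num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        fst_den = p1 * (1 - p2) + p2 * (1 - p1)
    rows = []
    for chrom in dict.fromkeys(G.chroms):
        on = np.asarray(G.chroms == chrom)
        pos0 = G.positions[on] - 1
        length = G.chrom_lengths.get(chrom, int(pos0.max()) + 1)
        he_c, num_c, den_c, ok_c = he_site[on], fst_num[on], fst_den[on], ok[on]
        win = pos0 // window_bp
        for w in range(-(-length // window_bp)):
            start = w * window_bp
            end = min(start + window_bp, length)
            inw = (win == w) & ok_c
            n_snps = int(inw.sum())
            if n_snps >= min_snps:
                he = float(np.mean(he_c[inw]))
                dsum = float(den_c[inw].sum())
                fst = float(num_c[inw].sum() / dsum) if dsum > 0 else np.nan
            else:
                he = fst = np.nan
            rows.append((chrom, start, end, n_snps, he, fst))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "he", "fst"])
    df["z_he"] = np.nan
    df["z_fst"] = np.nan
    df["selected"] = False
    return WindowTable(df).restandardize()


def call_selected_windows(
    tbl: WindowTable,
    z_fst_min: float = Z_FST_MIN_DEFAULT,
    z_he_max: float = Z_HE_MAX_DEFAULT,
) -> WindowTable:
    """Flag windows with Z_FST >= ``z_fst_min`` and Z_HE <= ``z_he_max``."""
    df = tbl.table.copy()
    df["selected"] = (df["z_fst"] >= z_fst_min) & (df["z_he"] <= z_he_max)
    return WindowTable(df)


def background_spectrum(G: GenotypeMatrix, pop: str | None = None) -> SiteFrequencySpectrum:
    """Genome-wide folded marginal SFS proportions: the neutral model of
    the CLR scan."""
    alt, n = G.allele_counts(pop)
    nmax = int(n.max()) if n.size else 0
    if nmax < 2:
        raise ValueError("need at least 2 haploid calls")
    # restrict to fully-called sites so all share one sample size
    full = n == nmax
    alt = alt[full]
    data = np.zeros(nmax + 1)
    np.add.at(data, alt, 1.0)
    spec = SiteFrequencySpectrum((pop or "ALL",), (nmax,), data).fold()
    return spec.normalized()


def _unfold_symmetric(bg: SiteFrequencySpectrum) -> np.ndarray:
    """Pseudo-unfolded background: folded mass split evenly between the
    two complementary derived counts."""
    n = bg.n_haploids[0]
    u = np.zeros(n + 1)
    for j in range(1, n):
        m = min(j, n - j)
        u[j] = bg.data[m] if 2 * m == n else bg.data[m] / 2.0
    return u


def _sweep_class_spectra(u_bg: np.ndarray, n: int) -> np.ndarray:
    """q[k, c]: P(folded minor count = c, site polymorphic | k of n
    lineages escaped).  Rows k = 0..n; columns c = 0..n//2.  Rows are NOT
    normalized: the lost monomorphic mass stays lost, so that conditioning
    on polymorphism can be applied to the full mixture over k."""
    half = n // 2
    out = np.zeros((n + 1, half + 1))
    j_old = np.arange(n + 1)
    for k in range(n + 1):
        if k == n:
            derived = u_bg.copy()
        else:
            # project the background onto k+1 lineages ...
            j_new = np.arange(k + 2)
            w = hypergeom.pmf(j_new[:, None], n, j_old[None, :], k + 1)
            proj = w @ u_bg
            # ... then replicate one uniformly chosen lineage n-k times
            derived = np.zeros(n + 1)
            for j in range(k + 2):
                pj = proj[j]
                if pj == 0:
                    continue
                p_derived_expanded = j / (k + 1)
                if j >= 1:
                    derived[(j - 1) + (n - k)] += pj * p_derived_expanded
                derived[j] += pj * (1.0 - p_derived_expanded)
        derived[0] = derived[n] = 0.0  # monomorphic outcomes drop out
        for j in range(1, n):
            out[k, min(j, n - j)] += derived[j]
    return out


def clr_scan(
    minor_counts: np.ndarray,
    positions: np.ndarray,
    background: SiteFrequencySpectrum,
    grid_points: np.ndarray | int = 50,
    alpha_grid: np.ndarray | None = None,
) -> SweepScanResult:
    """Composite likelihood ratio scan for selective sweeps.

    ``minor_counts`` are per-site folded minor-allele counts (full calls,
    sample size = the background's); ``positions`` their coordinates in bp.
    ``grid_points`` is either an explicit array of test positions or a
    number of equally spaced points across the scanned interval.
    """
    minor_counts = np.asarray(minor_counts, dtype=np.int64)
    positions = np.asarray(positions, dtype=np.float64)
    if minor_counts.shape != positions.shape:
        raise ValueError("minor_counts and positions must align")
    alpha_grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    n = background.n_haploids[0]
    if not background.folded:
        background = background.fold().normalized()
    if minor_counts.size == 0:
        empty = np.array([])
        return SweepScanResult(empty, empty.copy(), empty.copy(), background)
    if minor_counts.min() < 1 or minor_counts.max() > n // 2:
        raise ValueError("minor counts must lie in [1, n/2]")
    if isinstance(grid_points, (int, np.integer)):
        grid = np.linspace(positions.min(), positions.max(), int(grid_points))
    else:
        grid = np.asarray(grid_points, dtype=float)

    u_bg = _unfold_symmetric(background)
    q = _sweep_class_spectra(u_bg, n)  # (n+1, n//2+1)
    p_bg = background.data[minor_counts]
    if np.any(p_bg <= 0):
        raise ValueError("background spectrum has zero mass at an observed count")
    ll_bg = float(np.log(p_bg).sum())
    q_sel = q[:, minor_counts]  # (n+1, S)
    q_mass = q.sum(axis=1)  # polymorphic mass per escape class
    ks = np.arange(n + 1)

    # binomial pmf over escapee counts, computed in log space (fast path)
    log_choose = gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)

    def binom_weights(pe: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(ks[:, None] == 0, 0.0, ks[:, None] * np.log(pe[None, :]))
            lq = np.where(
                ks[:, None] == n, 0.0, (n - ks[:, None]) * np.log1p(-pe[None, :])
            )
        return np.exp(log_choose[:, None] + lp + lq)

    clr = np.zeros(len(grid))
    alpha_hat = np.zeros(len(grid))
    for gi, x in enumerate(grid):
        d = np.abs(positions - x)
        best_ll = ll_bg  # background-equivalent limit always included
        best_alpha = 0.0
        for alpha in alpha_grid:
            pe = -np.expm1(-alpha * d)  # escape probability per lineage
            w = binom_weights(pe)  # (n+1, S)
            # condition the mixture on the site being polymorphic
            norm = (w * q_mass[:, None]).sum(axis=0)
            if np.any(norm <= 0):
                continue
            p_site = (w * q_sel).sum(axis=0) / norm
            if np.any(p_site <= 0):
                continue
            ll = float(np.log(p_site).sum())
            if ll > best_ll:
                best_ll = ll
                best_alpha = float(alpha)
        # improvements below round-off are the background model in disguise
        gain = best_ll - ll_bg
        if gain <= 1e-8 * max(1.0, abs(ll_bg)):
            gain = 0.0
            best_alpha = 0.0
        clr[gi] = 2.0 * gain
        alpha_hat[gi] = best_alpha
    return SweepScanResult(grid, clr, alpha_hat, background)
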