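"""Diploid genotype matrix: the common currency of all statistics.

Genotypes are alternate-allele dosages in {0, 1, 2} with -1 for missing
calls.  Positions are 1-based within their chromosome (VCF convention);
window and BED coordinates produced downstream are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "MISSING"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    genotypes: np.ndarray  # (n_samples, n_sites) int8, -1 missing
    positions: np.ndarray  # (n_sites,) int64, 1-based
    chroms: np.ndarray  # (n_sites,) str
    samples: list[str]
    popmap: dict[str, str] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError("sample id count does not match genotype rows")
        if self.positions.shape != (m,) or self.chroms.shape != (m,):
            raise ValueError("positions/chroms do not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values restricted to {0,1,2,missing}")
        for c in dict.fromkeys(self.chroms):
            pos = self.positions[self.chroms == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.popmap.values()))

    def sample_indices(self, pop: str | None = None) -> np.ndarray:
        if pop is None:
            return np.arange(self.n_samples)
        idx = [i for i, s in enumerate(self.samples) if self.popmap.get(s) == pop]
        if not idx:
            raise KeyError(f"no samples assigned to population {pop!r}")
        return np.array(idx)

    def allele_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt_count, n_nonmissing_haploids) for a population."""
        g = self.genotypes[self.sample_indices(pop)]
        miss = g == MISSING
        alt = np.where(miss, 0, g).sum(axis=0)
        n = 2 * (~miss).sum(axis=0)
        return alt.astype(np.int64), n.astype(np.int64)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, mask],
            self.positions[mask],
            self.chroms[mask],
            list(self.samples),
            dict(self.popmap),
            dict(self.chrom_lengths),
        )

    def subset_samples(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        samples = [self.samples[i] for i in indices]
        return GenotypeMatrix(
            self.genotypes[indices],
            self.positions.copy(),
            self.chroms.copy(),
            samples,
            {s: self.popmap[s] for s in samples if s in self.popmap},
            dict(self.chrom_lengths),
        )
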