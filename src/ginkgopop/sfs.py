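"""Site frequency spectrum container (marginal or joint, folded or not).

``data[c1, ..., cd]`` holds the mass (branch length, site count or
probability) of sites whose alternate/derived allele count is ``c_k`` in
deme ``k``; axis ``k`` has length ``n_k + 1`` for ``n_k`` sampled haploids.
The two monomorphic corners (all zero / all fixed) are never part of the
polymorphic mass.  Folding is on the *global* minor allele: the cell ``c``
and its complement ``n - c`` are merged into whichever has total count
below half the total sample size (ties go to the lexicographically smaller
index vector).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

__all__ = ["SiteFrequencySpectrum", "write_sfs", "read_sfs"]


@dataclass
class SiteFrequencySpectrum:
    demes: tuple[str, ...]
    n_haploids: tuple[int, ...]
    data: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = tuple(n + 1 for n in self.n_haploids)
        if self.data.shape != expected:
            raise ValueError(
                f"SFS shape {self.data.shape} does not match sample sizes "
                f"{self.n_haploids} (expected {expected})"
            )
        if np.any(self.data < 0):
            raise ValueError("SFS entries must be >= 0")

    # ------------------------------------------------------------------

    @property
    def total_haploids(self) -> int:
        return int(sum(self.n_haploids))

    def _total_count_grid(self) -> np.ndarray:
        grids = np.indices(self.data.shape)
        return grids.sum(axis=0)

    def polymorphic_mask(self) -> np.ndarray:
        """True for cells that represent polymorphic sites."""
        tot = self._total_count_grid()
        mask = (tot > 0) & (tot < self.total_haploids)
        if self.folded:
            mask &= self._fold_keep_mask()
        return mask

    def _fold_keep_mask(self) -> np.ndarray:
        """Cells retained by the folding convention (minor side + tie cells
        that are lexicographically <= their complement)."""
        tot = self._total_count_grid()
        half = self.total_haploids / 2.0
        keep = tot < half
        if self.total_haploids % 2 == 0:
            for idx in np.argwhere(tot == self.total_haploids // 2):
                comp = tuple(n - i for n, i in zip(self.n_haploids, idx))
                if tuple(idx) <= comp:
                    keep[tuple(idx)] = True
        return keep

    def fold(self) -> "SiteFrequencySpectrum":
        """Merge each cell with its complement onto the minor-allele side."""
        if self.folded:
            return SiteFrequencySpectrum(
                self.demes, self.n_haploids, self.data.copy(), folded=True
            )
        flipped = self.data[tuple(slice(None, None, -1) for _ in self.data.shape)]
        keep = self._fold_keep_mask()
        tot = self._total_count_grid()
        out = np.zeros_like(self.data)
        out[keep] = self.data[keep] + flipped[keep]
        # self-complementary cell (exists only if every n_k is even): do not
        # double its own mass
        selfc = keep & (tot == self.total_haploids - tot)
        diag = np.array(
            [
                all(2 * i == n for i, n in zip(idx, self.n_haploids))
                for idx in np.argwhere(selfc)
            ],
            dtype=bool,
        )
        for idx in np.argwhere(selfc)[diag] if diag.size else []:
            out[tuple(idx)] = self.data[tuple(idx)]
        return SiteFrequencySpectrum(self.demes, self.n_haploids, out, folded=True)

    def normalized(self) -> "SiteFrequencySpectrum":
        """Probabilities over polymorphic cells (monomorphic cells masked)."""
        mask = self.polymorphic_mask()
        total = self.data[mask].sum()
        if total <= 0:
            raise ValueError("no polymorphic mass to normalize")
        out = np.zeros_like(self.data)
        out[mask] = self.data[mask] / total
        return SiteFrequencySpectrum(self.demes, self.n_haploids, out, self.folded)

    def marginalize(self, demes: tuple[str, ...] | list[str]) -> "SiteFrequencySpectrum":
        """Sum the joint spectrum down to the given subset of demes.

        Only defined for unfolded spectra (folding does not commute with
        marginalization)."""
        if self.folded:
            raise ValueError("cannot marginalize a folded spectrum")
        keep = [self.demes.index(d) for d in demes]
        axes = tuple(i for i in range(self.data.ndim) if i not in keep)
        data = self.data.sum(axis=axes)
        if keep != sorted(keep):
            order = sorted(keep)
            data = data.transpose([order.index(k) for k in keep])
        return SiteFrequencySpectrum(
            tuple(demes), tuple(self.n_haploids[i] for i in keep), data, False
        )

    def marginal(self, deme: str) -> "SiteFrequencySpectrum":
        """Single-deme marginal of an unfolded joint spectrum."""
        return self.marginalize((deme,))

    def project(self, n_new: int) -> "SiteFrequencySpectrum":
        """Hypergeometric projection of a 1-D spectrum down to ``n_new``
        haploids (average over subsamples without replacement)."""
        if self.data.ndim != 1:
            raise ValueError("projection implemented for 1-D spectra only")
        if self.folded:
            raise ValueError("project an unfolded spectrum, then fold")
        n = self.n_haploids[0]
        if not 1 <= n_new <= n:
            raise ValueError(f"cannot project {n} lineages to {n_new}")
        # W[j_new, j_old] = P(j_new of n_new | j_old of n)
        j_old = np.arange(n + 1)
        j_new = np.arange(n_new + 1)
        weights = hypergeom.pmf(j_new[:, None], n, j_old[None, :], n_new)
        return SiteFrequencySpectrum(
            self.demes, (n_new,), weights @ self.data, False
        )

    def copy(self) -> "SiteFrequencySpectrum":
        return SiteFrequencySpectrum(
            self.demes, self.n_haploids, self.data.copy(), self.folded
        )


# ---------------------------------------------------------------------------
# flat-text SFS format: optional '#' comment lines, then a header line with
# the per-deme haploid sample sizes, the folded/unfolded flag and the deme
# labels, then the row-major flattened entries (dadi/fastsimcoal style).
# ---------------------------------------------------------------------------

def write_sfs(sfs: SiteFrequencySpectrum, path: str | Path, comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        flag = "folded" if sfs.folded else "unfolded"
        fh.write(" ".join(str(n) for n in sfs.n_haploids) + f" {flag} " + " ".join(sfs.demes) + "\n")
        fh.write(" ".join(repr(float(x)) for x in sfs.data.ravel()) + "\n")


def read_sfs(path: str | Path) -> SiteFrequencySpectrum:
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header line and a data line")
    header = lines[0].split()
    sizes: list[int] = []
    i = 0
    while i < len(header) and header[i].isdigit():
        sizes.append(int(header[i]))
        i += 1
    if i >= len(header) or header[i] not in ("folded", "unfolded"):
        raise ValueError(f"{path}: header must contain 'folded' or 'unfolded'")
    folded = header[i] == "folded"
    demes = tuple(header[i + 1 :]) or tuple(f"pop{j}" for j in range(len(sizes)))
    if len(demes) != len(sizes):
        raise ValueError(f"{path}: {len(sizes)} sample sizes but {len(demes)} labels")
    values = np.fromstring(" ".join(lines[1:]), sep=" ")
    shape = tuple(n + 1 for n in sizes)
    if values.size != int(np.prod(shape)):
        raise ValueError(
            f"{path}: expected {int(np.prod(shape))} entries, found {values.size}"
        )
    return SiteFrequencySpectrum(demes, tuple(sizes), values.reshape(shape), folded)
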