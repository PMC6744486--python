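"""Structured-coalescent simulation for split/admixture demographies.

Backwards in time, lineages within a deme of diploid size N coalesce
pairwise at rate 1/(2N) per generation.  At a split time the child deme's
lineages move to the parent; at an admixture pulse each recipient lineage
independently chooses a source deme with the pulse fractions; size changes
switch a deme's N.  Simultaneous events are applied in a fixed documented
order (size changes, then pulses, then splits; ties by deme label).

Two routes are provided:

* :func:`simulate_genealogy` — a plain-Python simulator producing explicit
  genealogies (node times, leaf sets); it backs genotype simulation and
  serves as an internal cross-check of the fast path.
* :func:`simulate_sfs` — a numba-compiled kernel that accumulates branch
  lengths directly into the joint site-frequency-spectrum lattice over many
  replicates (the expected-SFS engine behind demographic fitting).

Both are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotypes import GenotypeMatrix
from .models import DemographicModel, ModelValidationError, SampleConfig
from .sfs import SiteFrequencySpectrum

__all__ = [
    "GenealogyNode",
    "Genealogy",
    "SweepInjection",
    "simulate_genealogy",
    "simulate_sfs",
    "simulate_genotypes",
]

# event codes shared by both simulator routes
_EV_SIZE = 0
_EV_PULSE = 1  # move each lineage of deme a to deme b with probability f
_EV_MOVE = 2  # move all lineages of deme a to deme b


def compile_events(model: DemographicModel) -> tuple[np.ndarray, ...]:
    """Flatten the model's demographic events into sorted parallel arrays
    of (time_generations, kind, deme_a, deme_b, value).

    A pulse with sources [(s1, f1), (s2, f2), ...] becomes a chain of
    conditional moves with renormalized fractions, ending in an
    unconditional move to the last source.
    """
    model.validate()
    idx = {d: i for i, d in enumerate(model.demes)}
    rows: list[tuple[float, int, int, int, float, int]] = []
    # the last tuple element is a stable sub-order so chained pulse moves
    # keep their sequence after sorting
    for sc in model.size_changes:
        rows.append((model.t_generations(sc.time_years), _EV_SIZE, idx[sc.deme], 0, sc.size, 0))
    for p in model.admixture_pulses:
        srcs = sorted(p.sources.items())  # deterministic label order
        t = model.t_generations(p.time_years)
        remaining = 1.0
        for j, (src, f) in enumerate(srcs):
            if j == len(srcs) - 1:
                rows.append((t, _EV_MOVE, idx[p.recipient], idx[src], 0.0, j))
            else:
                cond = 0.0 if remaining <= 0 else min(1.0, f / remaining)
                rows.append((t, _EV_PULSE, idx[p.recipient], idx[src], cond, j))
                remaining -= f
    for sp in model.splits:
        rows.append(
            (model.t_generations(sp.time_years), _EV_MOVE, idx[sp.child], idx[sp.parent], 0.0, 99)
        )
    rows.sort(key=lambda r: (r[0], r[1], r[5], r[2]))
    times = np.array([r[0] for r in rows], dtype=np.float64)
    kinds = np.array([r[1] for r in rows], dtype=np.int64)
    dema = np.array([r[2] for r in rows], dtype=np.int64)
    demb = np.array([r[3] for r in rows], dtype=np.int64)
    vals = np.array([r[4] for r in rows], dtype=np.float64)
    return times, kinds, dema, demb, vals


# ---------------------------------------------------------------------------
# explicit-genealogy route (plain Python)
# ---------------------------------------------------------------------------

@dataclass
class GenealogyNode:
    time: float  # generations before sampling
    deme: int  # deme index at birth (leaves) / at coalescence (internal)
    children: tuple["GenealogyNode", ...] = ()
    leaf_index: int = -1
    #: filled by Genealogy: sorted tuple of descendant leaf indices
    leaves: tuple[int, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Genealogy:
    """Binary coalescent tree over sampled haploid lineages.

    Leaves are at time 0 (ultrametric from sampling); branch lengths are in
    generations.  ``leaf_demes[i]`` is the deme index of leaf ``i``; leaves
    are numbered deme-major in sampling order.
    """

    root: GenealogyNode
    leaf_demes: np.ndarray
    demes: tuple[str, ...]

    def __post_init__(self) -> None:
        self._fill_leaves(self.root)

    def _fill_leaves(self, node: GenealogyNode) -> tuple[int, ...]:
        if node.is_leaf:
            node.leaves = (node.leaf_index,)
        else:
            acc: list[int] = []
            for c in node.children:
                acc.extend(self._fill_leaves(c))
            node.leaves = tuple(sorted(acc))
        return node.leaves

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_demes)

    def tmrca(self) -> float:
        return self.root.time

    def branches(self):
        """Yield (node, branch_length) for every non-root node."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                yield c, node.time - c.time
                stack.append(c)

    def total_branch_length(self) -> float:
        return sum(bl for _, bl in self.branches())


def simulate_genealogy(
    model: DemographicModel, samples: SampleConfig, seed: int | None = None
) -> Genealogy:
    """Draw one genealogy from the structured coalescent."""
    rng = np.random.default_rng(seed)
    return _simulate_genealogy_rng(model, samples, rng)


def _simulate_genealogy_rng(
    model: DemographicModel, samples: SampleConfig, rng: np.random.Generator
) -> Genealogy:
    model.validate()
    n_demes = len(model.demes)
    times, kinds, dema, demb, vals = compile_events(model)
    sizes = np.array([model.sizes[d] for d in model.demes], dtype=float)

    active: list[list[GenealogyNode]] = [[] for _ in range(n_demes)]
    leaf_demes: list[int] = []
    li = 0
    for di, d in enumerate(model.demes):
        for _ in range(samples.n_haploids(d)):
            active[di].append(GenealogyNode(time=0.0, deme=di, leaf_index=li))
            leaf_demes.append(di)
            li += 1
    if li < 2:
        raise ValueError("need at least 2 sampled lineages")

    t = 0.0
    ev = 0
    n_active = li
    while n_active > 1:
        rates = np.array(
            [len(a) * (len(a) - 1) / (4.0 * sizes[d]) for d, a in enumerate(active)]
        )
        total = rates.sum()
        t_next_ev = times[ev] if ev < len(times) else math.inf
        if total <= 0.0:
            if math.isinf(t_next_ev):
                raise ModelValidationError(
                    "lineages trapped in separate demes with no ancestral path"
                )
            t = t_next_ev
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_next_ev:
                t = t_next_ev
            else:
                t += wait
                d = int(rng.choice(n_demes, p=rates / total))
                group = active[d]
                i, j = rng.choice(len(group), size=2, replace=False)
                i, j = (int(i), int(j)) if i < j else (int(j), int(i))
                a, b = group[i], group[j]
                del group[j], group[i]
                group.append(GenealogyNode(time=t, deme=d, children=(a, b)))
                n_active -= 1
                continue
        # apply all events at this time
        while ev < len(times) and times[ev] <= t:
            k, a, b, v = kinds[ev], int(dema[ev]), int(demb[ev]), vals[ev]
            if k == _EV_SIZE:
                sizes[a] = v
            elif k == _EV_MOVE:
                active[b].extend(active[a])
                active[a] = []
            elif k == _EV_PULSE:
                stay: list[GenealogyNode] = []
                for node in active[a]:
                    if rng.random() < v:
                        active[b].append(node)
                    else:
                        stay.append(node)
                active[a] = stay
            ev += 1

    root = next(node for group in active for node in group)
    return Genealogy(root=root, leaf_demes=np.array(leaf_demes), demes=model.demes)


# ---------------------------------------------------------------------------
# fast SFS route (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sfs_kernel(
    n_demes,
    sample_counts,  # (n_demes,) haploids at t=0
    init_sizes,  # (n_demes,)
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    n_reps,
    seed,
    strides,  # (n_demes,) row-major strides of the SFS lattice
    sfs_flat,  # output accumulator, flattened lattice
):
    np.random.seed(seed)
    n_tot = 0
    for d in range(n_demes):
        n_tot += sample_counts[d]
    max_nodes = 2 * n_tot
    counts = np.zeros((max_nodes, n_demes), dtype=np.int64)
    birth = np.zeros(max_nodes, dtype=np.float64)
    members = np.zeros((n_demes, n_tot), dtype=np.int64)
    k_in = np.zeros(n_demes, dtype=np.int64)
    sizes = np.zeros(n_demes, dtype=np.float64)
    rates = np.zeros(n_demes, dtype=np.float64)
    n_events = ev_time.shape[0]

    for rep in range(n_reps):
        # reset state
        for d in range(n_demes):
            sizes[d] = init_sizes[d]
            k_in[d] = 0
        nid = 0
        for d in range(n_demes):
            for _ in range(sample_counts[d]):
                for dd in range(n_demes):
                    counts[nid, dd] = 0
                counts[nid, d] = 1
                birth[nid] = 0.0
                members[d, k_in[d]] = nid
                k_in[d] += 1
                nid += 1
        t = 0.0
        ev = 0
        n_active = n_tot
        while n_active > 1:
            total = 0.0
            for d in range(n_demes):
                k = k_in[d]
                r = k * (k - 1) / (4.0 * sizes[d])
                rates[d] = r
                total += r
            t_next = ev_time[ev] if ev < n_events else np.inf
            coalesced = False
            if total <= 0.0:
                if t_next == np.inf:
                    return -1  # trapped lineages
                t = t_next
            else:
                wait = np.random.exponential(1.0 / total)
                if t + wait >= t_next:
                    t = t_next
                else:
                    t = t + wait
                    # choose deme proportional to rate
                    u = np.random.random() * total
                    acc = 0.0
                    d = 0
                    for dd in range(n_demes):
                        acc += rates[dd]
                        if u < acc:
                            d = dd
                            break
                    k = k_in[d]
                    i = np.random.randint(k)
                    j = np.random.randint(k - 1)
                    if j >= i:
                        j += 1
                    if j < i:
                        i, j = j, i
                    a = members[d, i]
                    b = members[d, j]
                    # record both child branches into the SFS lattice
                    cell_a = 0
                    cell_b = 0
                    for dd in range(n_demes):
                        cell_a += counts[a, dd] * strides[dd]
                        cell_b += counts[b, dd] * strides[dd]
                    sfs_flat[cell_a] += t - birth[a]
                    sfs_flat[cell_b] += t - birth[b]
                    # merge
                    for dd in range(n_demes):
                        counts[nid, dd] = counts[a, dd] + counts[b, dd]
                    birth[nid] = t
                    # remove j (j > i) by swapping in the last element, then
                    # remove i the same way, then append the merged node
                    members[d, j] = members[d, k - 1]
                    members[d, i] = members[d, k - 2]
                    members[d, k - 2] = nid
                    k_in[d] = k - 1
                    nid += 1
                    n_active -= 1
                    coalesced = True
            if not coalesced:
                while ev < n_events and ev_time[ev] <= t:
                    kk = ev_kind[ev]
                    a = ev_a[ev]
                    b = ev_b[ev]
                    v = ev_val[ev]
                    if kk == 0:  # size change
                        sizes[a] = v
                    elif kk == 2:  # move all a -> b
                        for m in range(k_in[a]):
                            members[b, k_in[b]] = members[a, m]
                            k_in[b] += 1
                        k_in[a] = 0
                    else:  # pulse: each lineage of a -> b with prob v
                        w = 0
                        for m in range(k_in[a]):
                            node = members[a, m]
                            if np.random.random() < v:
                                members[b, k_in[b]] = node
                                k_in[b] += 1
                            else:
                                members[a, w] = node
                                w += 1
                        k_in[a] = w
                    ev += 1
    return 0


def simulate_sfs(
    model: DemographicModel,
    samples: SampleConfig,
    n_replicates: int,
    folded: bool = False,
    seed: int | None = None,
    normalized: bool = True,
) -> SiteFrequencySpectrum:
    """Monte-Carlo expected SFS from coalescent branch lengths.

    Every branch of every replicate genealogy contributes its length (in
    generations) to the lattice cell indexed by its number of descendant
    leaves per deme.  With ``normalized=True`` the polymorphic cells are
    scaled to sum to 1 (the expected *shape* of the spectrum); otherwise
    the raw mean branch length per cell is returned.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model.validate()
    demes = model.demes
    n_hap = tuple(samples.n_haploids(d) for d in demes)
    shape = tuple(n + 1 for n in n_hap)
    strides = np.array(
        [int(np.prod(shape[i + 1 :], dtype=np.int64)) for i in range(len(shape))],
        dtype=np.int64,
    )
    times, kinds, dema, demb, vals = compile_events(model)
    sfs_flat = np.zeros(int(np.prod(shape)), dtype=np.float64)
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    status = _sfs_kernel(
        len(demes),
        np.array(n_hap, dtype=np.int64),
        np.array([model.sizes[d] for d in demes], dtype=np.float64),
        times,
        kinds,
        dema,
        demb,
        vals,
        int(n_replicates),
        int(seed) % (2**31),
        strides,
        sfs_flat,
    )
    if status != 0:
        raise ModelValidationError(
            "lineages trapped in separate demes with no ancestral path"
        )
    spec = SiteFrequencySpectrum(demes, n_hap, sfs_flat.reshape(shape) / n_replicates)
    if folded:
        spec = spec.fold()
    if normalized:
        spec = spec.normalized()
    return spec


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepInjection:
    """Replace the frequency spectrum of sites inside ``[start_bp, end_bp)``
    (0-based, on the concatenated coordinate system) with a
    high-frequency-derived, diversity-depleted one: each site keeps its
    background frequency with probability ``escape_fraction`` and is
    otherwise set to a derived count drawn uniformly from {n-1, n} (count
    n fixes the site, which is then dropped — the diversity depletion)."""

    start_bp: int
    end_bp: int
    escape_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError("need 0 <= start_bp < end_bp")
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must be in [0, 1]")


def simulate_genotypes(
    model: DemographicModel,
    samples: SampleConfig,
    n_loci: int,
    locus_length_bp: int,
    seed: int | None = None,
    sweep_injection: SweepInjection | None = None,
    layout: str = "loci",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Simulate diploid genotypes at independent non-recombining loci.

    For each locus a genealogy is drawn, mutations fall as a Poisson
    process at rate mu_gen * locus_length * total branch length and are
    placed at distinct uniform positions; infinite-sites, so each site is
    biallelic with the derived allele carried by the leaves under one
    branch.  Haploids are paired into diploid individuals within demes.

    ``layout="loci"`` emits one chromosome per locus; ``layout="concat"``
    lays loci end-to-end on a single chromosome ``chr1`` (loci remain
    unlinked — free recombination between loci).  ``missing_rate`` masks
    genotype calls uniformly at random.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if locus_length_bp < 1:
        raise ValueError("locus_length_bp must be >= 1")
    if samples.total_haploids < 2:
        raise ValueError("need at least one diploid sample")
    if layout not in ("loci", "concat"):
        raise ValueError("layout must be 'loci' or 'concat'")
    if sweep_injection is not None and layout != "concat":
        raise ValueError("sweep injection requires layout='concat'")
    model.validate()
    rng = np.random.default_rng(seed)
    mu_gen = model.mu_per_generation
    n_hap = samples.total_haploids
    demes_sampled = [d for d in model.demes if samples.n_haploids(d) > 0]

    sample_ids: list[str] = []
    popmap: dict[str, str] = {}
    for d in demes_sampled:
        for k in range(samples.diploids.get(d, 0)):
            sid = f"{d}_{k + 1:03d}"
            sample_ids.append(sid)
            popmap[sid] = d

    hap_cols: list[np.ndarray] = []
    positions: list[int] = []
    chroms: list[str] = []
    for locus in range(n_loci):
        gen = _simulate_genealogy_rng(model, samples, rng)
        branches = list(gen.branches())
        lengths = np.array([bl for _, bl in branches])
        total_bl = lengths.sum()
        n_mut = rng.poisson(mu_gen * locus_length_bp * total_bl)
        n_mut = min(n_mut, locus_length_bp)  # distinct positions cap
        if n_mut == 0:
            continue
        pos = np.sort(rng.choice(locus_length_bp, size=n_mut, replace=False)) + 1
        which = rng.choice(len(branches), size=n_mut, p=lengths / total_bl)
        offset = locus * locus_length_bp if layout == "concat" else 0
        chrom = "chr1" if layout == "concat" else f"locus_{locus + 1:04d}"
        for p, bi in zip(pos, which):
            carriers = np.zeros(n_hap, dtype=bool)
            carriers[list(branches[bi][0].leaves)] = True
            abs_pos0 = offset + int(p) - 1  # 0-based concatenated coordinate
            if (
                sweep_injection is not None
                and sweep_injection.start_bp <= abs_pos0 < sweep_injection.end_bp
                and rng.random() >= sweep_injection.escape_fraction
            ):
                m = n_hap - 1 + int(rng.integers(2))
                if m >= n_hap:
                    continue  # fixed by the sweep: site lost
                carriers = np.zeros(n_hap, dtype=bool)
                carriers[rng.choice(n_hap, size=m, replace=False)] = True
            hap_cols.append(carriers)
            positions.append(offset + int(p))
            chroms.append(chrom)

    if hap_cols:
        haps = np.array(hap_cols, dtype=np.int8).T  # (n_hap, n_sites)
        geno = haps[0::2] + haps[1::2]
    else:
        geno = np.zeros((n_hap // 2, 0), dtype=np.int8)
    if missing_rate > 0.0 and geno.size:
        mask = rng.random(geno.shape) < missing_rate
        geno = np.where(mask, np.int8(-1), geno)
        keep = (geno >= 0).any(axis=0)
        geno = geno[:, keep]
        positions = [p for p, k in zip(positions, keep) if k]
        chroms = [c for c, k in zip(chroms, keep) if k]

    if layout == "concat":
        chrom_lengths = {"chr1": n_loci * locus_length_bp}
    else:
        chrom_lengths = {
            f"locus_{i + 1:04d}": locus_length_bp for i in range(n_loci)
        }
    return GenotypeMatrix(
        geno,
        np.array(positions, dtype=np.int64),
        np.array(chroms, dtype=object),
        sample_ids,
        popmap,
        chrom_lengths,
    )
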