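"""Sample relatedness and ancestry inference.

* :func:`pca` — eigendecomposition of the variance-standardized genotype
  relationship matrix (PLINK ``--pca`` convention).
* :func:`nj_tree` — Saitou-Nei neighbor joining with the Studier-Keppler
  Q-criterion and deterministic lexicographic tie-breaking.
* :func:`admixture_fit` / :func:`admixture_cv` — maximum-likelihood
  ancestry estimation under the binomial admixture model (ADMIXTURE/frappe)
  by EM block relaxation, with genotype-entry-masking cross-validation for
  choosing the number of ancestral components K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .stats import DistanceMatrix

__all__ = [
    "PcaResult",
    "PhyloNode",
    "PhyloTree",
    "AncestryFit",
    "pca",
    "nj_tree",
    "admixture_fit",
    "admixture_cv",
]

_P_CLIP = 1e-6  # allele-frequency clip keeping the likelihood finite


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    samples: list[str]
    eigenvectors: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray  # (n_components,) non-increasing
    percent_variance: np.ndarray  # eigenvalue / trace * 100


def pca(G: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the variance-standardized relationship matrix.

    Each site is standardized as (g - 2p) / sqrt(2p(1-p)); missing entries
    are mean-imputed (zero after centering); monomorphic sites dropped;
    the relationship matrix is X X^T / M over the M retained sites.
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = G.genotypes.astype(float)
    present = g != MISSING
    alt = np.where(present, g, 0.0).sum(axis=0)
    n = 2.0 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic: nothing to decompose")
    p = p[poly]
    x = np.where(present, g, np.nan)[:, poly]
    x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x = np.nan_to_num(x, nan=0.0)
    m = x.shape[1]
    grm = x @ x.T / m
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    trace = np.clip(np.trace(grm), np.finfo(float).tiny, None)
    # deterministic sign: largest-magnitude loading positive
    vecs = vecs[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcaResult(
        samples=list(G.samples),
        eigenvectors=vecs,
        eigenvalues=vals[:k],
        percent_variance=100.0 * vals[:k] / trace,
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    name: str = ""
    length: float = 0.0  # branch length to parent
    children: list["PhyloNode"] = field(default_factory=list)

    #: smallest leaf label underneath; used for deterministic tie-breaks
    def min_leaf(self) -> str:
        if not self.children:
            return self.name
        return min(c.min_leaf() for c in self.children)

    def to_newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.to_newick() for c in self.children)
        if self.length or self.name:
            return f"({inner}){self.name}:{self.length:.10g}"
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree serialized with a trifurcating root (newick)."""

    root: PhyloNode

    @property
    def newick(self) -> str:
        return self.root.to_newick() + ";"

    def leaf_names(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.children:
                out.append(node.name)
            stack.extend(node.children)
        return sorted(out)

    @property
    def has_negative_lengths(self) -> bool:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.length < 0:
                return True
            stack.extend(node.children)
        return False


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on an IBS distance matrix.

    Uses the Studier-Keppler criterion Q_ij = (r-2) d_ij - R_i - R_j; ties
    are broken by the lexicographically smallest pair of (smallest leaf
    label under each node).  Negative branch lengths are retained and
    flagged on the tree.
    """
    n = len(D.samples)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    d = np.array(D.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    nodes: list[PhyloNode] = [PhyloNode(name=s) for s in D.samples]

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            (tuple(sorted((nodes[i].min_leaf(), nodes[j].min_leaf()))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = pairs[0]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        parent = PhyloNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    # final star resolution over the remaining three nodes
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    return PhyloTree(root=PhyloNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# ancestry estimation (binomial admixture model)
# ---------------------------------------------------------------------------

@dataclass
class AncestryFit:
    K: int
    samples: list[str]
    Q: np.ndarray  # (n_samples, K) ancestry fractions, rows sum to 1
    P: np.ndarray  # (K, n_sites) component allele frequencies
    loglik: float
    loglik_trace: np.ndarray
    n_iterations: int
    converged: bool
    seed: int | None


def _admixture_loglik(g, present, Q, P):
    pi = np.clip(Q @ P, _P_CLIP, 1.0 - _P_CLIP)
    terms = np.where(present, g * np.log(pi) + (2.0 - g) * np.log1p(-pi), 0.0)
    return float(terms.sum())


def admixture_fit(
    G: GenotypeMatrix,
    K: int,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_replicates: int = 1,
) -> AncestryFit:
    """Maximum-likelihood ancestry fractions under the binomial admixture
    model, log L = sum_{i,s} [g ln(q_i . p_s) + (2-g) ln(1 - q_i . p_s)]
    (binomial coefficient omitted, as is conventional).

    EM block relaxation (frappe-type multiplicative updates) from a seeded
    random start; the best of ``n_replicates`` restarts is returned.  The
    log-likelihood is non-decreasing along the recorded trace.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    g = G.genotypes.astype(float)
    present = g != MISSING
    g = np.where(present, g, 0.0)
    m_i = present.sum(axis=1, keepdims=True).astype(float)  # sites per sample
    if np.any(m_i == 0):
        raise ValueError("sample with no called genotypes")

    best: AncestryFit | None = None
    for _rep in range(max(1, n_replicates)):
        if K == 1:
            alt = g.sum(axis=0)
            n = 2.0 * present.sum(axis=0)
            P = np.clip(alt / np.maximum(n, 1), _P_CLIP, 1 - _P_CLIP)[None, :]
            Q = np.ones((G.n_samples, 1))
            ll = _admixture_loglik(g, present, Q, P)
            fit = AncestryFit(K, list(G.samples), Q, P, ll, np.array([ll]), 0, True, seed)
        else:
            Q = rng.dirichlet(np.ones(K), size=G.n_samples)
            P = np.clip(rng.uniform(0.05, 0.95, size=(K, G.n_sites)), _P_CLIP, 1 - _P_CLIP)
            trace = []
            converged = False
            it = 0
            for it in range(1, max_iter + 1):
                pi = np.clip(Q @ P, _P_CLIP, 1.0 - _P_CLIP)
                A = np.where(present, g / pi, 0.0)
                B = np.where(present, (2.0 - g) / (1.0 - pi), 0.0)
                # E-step responsibilities folded into multiplicative updates
                QA = Q.T @ A  # (K, S)
                QB = Q.T @ B
                num = P * QA
                den = num + (1.0 - P) * QB
                with np.errstate(invalid="ignore", divide="ignore"):
                    P = np.clip(np.where(den > 0, num / den, P), _P_CLIP, 1 - _P_CLIP)
                Q = Q * (A @ P.T + B @ (1.0 - P).T) / (2.0 * m_i)
                Q = np.clip(Q, 0.0, None)
                Q /= Q.sum(axis=1, keepdims=True)
                ll = _admixture_loglik(g, present, Q, P)
                if trace and ll - trace[-1] < tol:
                    trace.append(ll)
                    converged = True
                    break
                trace.append(ll)
            fit = AncestryFit(
                K, list(G.samples), Q, P, trace[-1], np.array(trace), it, converged, seed
            )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def admixture_cv(
    G: GenotypeMatrix,
    K_range: list[int],
    n_folds: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> dict[int, float]:
    """Cross-validation error per K by genotype-entry masking.

    Non-missing entries are randomly partitioned into ``n_folds`` folds;
    each fold is masked in turn, the model is refitted on the rest, and the
    masked entries are scored by squared error against the expected
    genotype 2 q_i . p_s.  Returns the mean error per K.
    """
    rng = np.random.default_rng(seed)
    present = G.genotypes != MISSING
    entry_fold = rng.integers(n_folds, size=G.genotypes.shape)
    errors: dict[int, float] = {}
    for K in K_range:
        fold_errs = []
        for f in range(n_folds):
            mask = present & (entry_fold == f)
            if not mask.any():
                continue
            train = G.genotypes.copy()
            train[mask] = MISSING
            if not (train != MISSING).any(axis=1).all():
                raise ValueError("a fold left a sample with no training entries")
            Gt = GenotypeMatrix(
                train, G.positions, G.chroms, list(G.samples), dict(G.popmap),
                dict(G.chrom_lengths),
            )
            fit = admixture_fit(Gt, K, seed=int(rng.integers(2**31)), **fit_kwargs)
            expected = 2.0 * np.clip(fit.Q @ fit.P, 0.0, 1.0)
            err = np.mean((G.genotypes[mask].astype(float) - expected[mask]) ** 2)
            fold_errs.append(err)
        if not fold_errs:
            raise ValueError("no scoreable entries in any fold")
        errors[K] = float(np.mean(fold_errs))
    return errors
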