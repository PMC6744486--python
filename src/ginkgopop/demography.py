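"""SFS composite-likelihood demographic inference.

The fitting machinery mirrors the fastsimcoal2 workflow: an expected joint
SFS is computed by coalescent simulation, the observed SFS is scored with
a multinomial composite log-likelihood over polymorphic cells, free
parameters are maximized by cyclic conditional 1-D searches (ECM-style)
with common random numbers stabilizing the Monte-Carlo objective, models
are compared by AIC and Akaike weights, and confidence intervals come from
a parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .coalescent import simulate_sfs
from .models import (
    DemographicModel,
    SampleConfig,
    build_ginkgo_model,
)
from .sfs import SiteFrequencySpectrum

__all__ = [
    "ModelTemplate",
    "FitResult",
    "ModelComparison",
    "BootstrapResult",
    "expected_sfs",
    "pairwise_spectra",
    "composite_loglik",
    "fit_model",
    "compare_models",
    "parametric_bootstrap",
    "ginkgo_admixture_template",
    "ginkgo_no_admixture_template",
    "constant_size_template",
]


# ---------------------------------------------------------------------------
# model templates
# ---------------------------------------------------------------------------

@dataclass
class ModelTemplate:
    """A demographic model with named free parameters.

    ``builder`` maps a full parameter dict to a DemographicModel;
    ``free_params`` maps names to (lower, upper) bounds; ``log_scale``
    marks parameters searched on a log10 grid (sizes and times) versus a
    linear one (fractions).
    """

    name: str
    builder: Callable[[dict[str, float]], DemographicModel]
    free_params: dict[str, tuple[float, float]]
    fixed_params: dict[str, float] = field(default_factory=dict)
    log_scale: dict[str, bool] = field(default_factory=dict)

    def build(self, free: dict[str, float]) -> DemographicModel:
        params = dict(self.fixed_params)
        params.update(free)
        return self.builder(params)

    def is_log(self, name: str) -> bool:
        return self.log_scale.get(name, True)


def ginkgo_admixture_template(
    free_params: dict[str, tuple[float, float]] | None = None,
    **fixed_overrides: float,
) -> ModelTemplate:
    """The four-lineage split-plus-admixture ginkgo model.

    Recognized parameter names: ``f_south`` (NORTH ancestry fraction from
    SOUTH), ``t_split_swest``, ``t_split_south``, ``t_pulse_north`` (years),
    ``ancestral_ne``, ``descendant_ne`` and per-deme sizes ``EAST``,
    ``SOUTH``, ``NORTH``, ``SWEST`` (diploids).  Parameters not listed as
    free stay at the study's best-fit values (or ``fixed_overrides``).
    """
    free_params = dict(free_params or {})

    def builder(params: dict[str, float]) -> DemographicModel:
        return build_ginkgo_model(**params)

    log_scale = {name: name != "f_south" for name in free_params}
    return ModelTemplate(
        name="ginkgo_admixture",
        builder=builder,
        free_params=free_params,
        fixed_params=dict(fixed_overrides),
        log_scale=log_scale,
    )


def ginkgo_no_admixture_template(
    free_params: dict[str, tuple[float, float]] | None = None,
    **fixed_overrides: float,
) -> ModelTemplate:
    """Bifurcating alternative: NORTH splits from SOUTH (no pulse)."""
    free_params = dict(free_params or {})

    def builder(params: dict[str, float]) -> DemographicModel:
        p = dict(params)
        t_north = p.pop("t_split_north", 139_260.0)
        model = build_ginkgo_model(**p, f_south=1.0)
        # replace the degenerate pulse with a clean split
        model.admixture_pulses.clear()
        from .models import Split

        model.splits.append(Split(float(t_north), "NORTH", "SOUTH"))
        model.splits.sort(key=lambda s: -s.time_years)
        model.validate()
        return model

    return ModelTemplate(
        name="ginkgo_no_admixture",
        builder=builder,
        free_params=free_params,
        fixed_params=dict(fixed_overrides),
        log_scale={name: True for name in free_params},
    )


def constant_size_template(
    free_params: dict[str, tuple[float, float]] | None = None,
    demes: tuple[str, ...] = ("POP",),
) -> ModelTemplate:
    """Single panmictic deme of constant size ``ne``."""
    if free_params is None:
        free_params = {"ne": (1e3, 1e6)}
    free_params = dict(free_params)

    def builder(params: dict[str, float]) -> DemographicModel:
        ne = params.get("ne", 50_514.0)
        return DemographicModel(demes=demes, sizes={d: float(ne) for d in demes})

    return ModelTemplate(
        name="constant_size",
        builder=builder,
        free_params=free_params,
        log_scale={name: True for name in free_params},
    )


# ---------------------------------------------------------------------------
# expected SFS and the composite likelihood
# ---------------------------------------------------------------------------

def _floor_normalize(spec: SiteFrequencySpectrum, n_sims: int) -> SiteFrequencySpectrum:
    """Zero polymorphic cells floored at 1/(10 n_sims n_cells), then
    renormalized (likelihood-finiteness guard)."""
    mask = spec.polymorphic_mask()
    floor = 1.0 / (10.0 * n_sims * mask.sum())
    total = spec.data[mask].sum()
    if total <= 0:
        raise ValueError("expected SFS has no polymorphic mass")
    spec.data[mask] /= total
    spec.data[mask & (spec.data < floor)] = floor
    spec.data[mask] /= spec.data[mask].sum()
    return spec


def expected_sfs(
    model: DemographicModel,
    samples: SampleConfig,
    n_sims: int,
    seed: int | None = None,
    folded: bool = False,
) -> SiteFrequencySpectrum:
    """Monte-Carlo expected SFS with the zero-cell floor applied."""
    return _floor_normalize(
        simulate_sfs(model, samples, n_sims, folded=folded, seed=seed), n_sims
    )


def pairwise_spectra(
    joint: SiteFrequencySpectrum, fold: bool = True
) -> list[SiteFrequencySpectrum]:
    """All two-deme marginal spectra of an unfolded joint SFS (the 2D-SFS
    decomposition used by the summed-pairwise composite likelihood)."""
    import itertools

    if joint.folded:
        raise ValueError("pairwise extraction needs the unfolded joint SFS")
    out = []
    for pair in itertools.combinations(joint.demes, 2):
        s = joint.marginalize(pair)
        out.append(s.fold() if fold else s)
    return out


def composite_loglik(
    obs: SiteFrequencySpectrum, exp: SiteFrequencySpectrum
) -> float:
    """Multinomial composite log-likelihood over polymorphic cells:
    ln L = sum m_cell ln p_cell for cells with observed mass m_cell > 0."""
    if obs.demes != exp.demes or obs.n_haploids != exp.n_haploids:
        raise ValueError("observed and expected SFS lattices do not match")
    if obs.folded != exp.folded:
        raise ValueError("observed and expected SFS must share folding")
    mask = obs.polymorphic_mask() & (obs.data > 0)
    p = exp.data[mask]
    if np.any(p <= 0):
        raise ValueError(
            "expected SFS has zero mass in an observed cell; apply the floor "
            "(use expected_sfs)"
        )
    return float(np.sum(obs.data[mask] * np.log(p)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    template: str
    param_names: list[str]
    estimates: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    loglik: float
    n_free: int
    n_sims: int
    n_restarts: int
    restart_logliks: list[float]
    seed: int | None
    n_failed_evals: int = 0


def _search_grid(lo: float, hi: float, n: int, log: bool) -> np.ndarray:
    if log:
        return np.logspace(math.log10(lo), math.log10(hi), n)
    return np.linspace(lo, hi, n)


def fit_model(
    obs_sfs: SiteFrequencySpectrum,
    template: ModelTemplate,
    samples: SampleConfig | None = None,
    n_restarts: int = 3,
    n_sims: int = 20_000,
    seed: int | None = None,
    n_coarse: int = 13,
    n_refine: int = 11,
    max_cycles: int = 3,
    tol: float = 0.5,
    sfs_mode: str = "joint",
) -> FitResult:
    """Maximize the composite likelihood over the template's free
    parameters by cyclic conditional 1-D maximization (ECM-style).

    Each 1-D step is a two-stage bracketed grid search (coarse scan over
    the bounds, then refinement around the best point).  Every objective
    evaluation within a cycle reuses one simulation seed (common random
    numbers); a fresh batch is drawn between cycles.  The best of
    ``n_restarts`` independently started restarts is returned.

    ``sfs_mode="joint"`` scores the full joint SFS; ``"pairwise"`` sums
    the composite log-likelihoods of all folded two-deme marginal (2D)
    spectra, which is far better populated at moderate sample sizes (and
    mirrors the 2D-SFS construction of the fastsimcoal workflow).  In
    pairwise mode ``obs_sfs`` must be the *unfolded* joint spectrum; the
    folding is applied per pair.
    """
    if sfs_mode not in ("joint", "pairwise"):
        raise ValueError("sfs_mode must be 'joint' or 'pairwise'")
    if not template.free_params:
        # degenerate: no search, just evaluate the fixed model
        model = template.build({})
        smp = samples or _samples_from_sfs(obs_sfs)
        exp = expected_sfs(model, smp, n_sims, seed=seed, folded=obs_sfs.folded)
        ll = composite_loglik(obs_sfs, exp)
        return FitResult(
            template.name, [], {}, {}, ll, 0, n_sims, 0, [ll], seed
        )
    smp = samples or _samples_from_sfs(obs_sfs)
    rng = np.random.default_rng(seed)
    names = list(template.free_params)

    if sfs_mode == "pairwise":
        obs_pairs = pairwise_spectra(obs_sfs, fold=True)

    failures: list[tuple[dict[str, float], str]] = []

    def objective(free: dict[str, float], batch_seed: int) -> float:
        # an invalid parameter combination (e.g. a split searched past the
        # event that depends on it) scores -inf and the search continues
        try:
            model = template.build(free)
            if sfs_mode == "pairwise":
                joint = simulate_sfs(model, smp, n_sims, folded=False, seed=batch_seed)
                ll = 0.0
                for obs_p, exp_p in zip(obs_pairs, pairwise_spectra(joint, fold=True)):
                    ll += composite_loglik(obs_p, _floor_normalize(exp_p, n_sims))
                return ll
            exp = expected_sfs(
                model, smp, n_sims, seed=batch_seed, folded=obs_sfs.folded
            )
            return composite_loglik(obs_sfs, exp)
        except (ValueError, ArithmeticError) as err:
            failures.append((dict(free), str(err)))
            return -math.inf

    best: tuple[float, dict[str, float]] | None = None
    restart_lls: list[float] = []
    for _restart in range(max(1, n_restarts)):
        current: dict[str, float] = {}
        for name in names:
            lo, hi = template.free_params[name]
            if template.is_log(name):
                current[name] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            else:
                current[name] = rng.uniform(lo, hi)
        ll_prev: float | None = None
        ll = -math.inf
        for _cycle in range(max_cycles):
            batch_seed = int(rng.integers(2**31))
            for name in names:
                lo, hi = template.free_params[name]
                log = template.is_log(name)
                grid = _search_grid(lo, hi, n_coarse, log)
                lls = [
                    objective({**current, name: float(v)}, batch_seed) for v in grid
                ]
                k = int(np.argmax(lls))
                # refine between the neighbors of the coarse optimum
                rlo = grid[max(k - 1, 0)]
                rhi = grid[min(k + 1, len(grid) - 1)]
                fine = _search_grid(rlo, rhi, n_refine, log)
                flls = [
                    objective({**current, name: float(v)}, batch_seed) for v in fine
                ]
                kf = int(np.argmax(flls))
                current[name] = float(fine[kf])
                ll = float(flls[kf])
            if ll_prev is not None and abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
        restart_lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, dict(current))
    assert best is not None
    if not math.isfinite(best[0]):
        detail = f": last failure: {failures[-1][1]}" if failures else ""
        raise ValueError(
            "every objective evaluation failed (incompatible template, "
            f"sample configuration or observed SFS?){detail}"
        )
    return FitResult(
        template=template.name,
        param_names=names,
        estimates=best[1],
        bounds=dict(template.free_params),
        loglik=best[0],
        n_free=len(names),
        n_sims=n_sims,
        n_restarts=n_restarts,
        restart_logliks=restart_lls,
        seed=seed,
        n_failed_evals=len(failures),
    )


def _samples_from_sfs(sfs: SiteFrequencySpectrum) -> SampleConfig:
    if any(n % 2 for n in sfs.n_haploids):
        raise ValueError("odd haploid sample size: pass samples explicitly")
    return SampleConfig({d: n // 2 for d, n in zip(sfs.demes, sfs.n_haploids)})


# ---------------------------------------------------------------------------
# model comparison and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    table: "pd.DataFrame"  # noqa: F821  (columns: model, k, loglik, aic, delta_aic, weight)


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """AIC = 2k - 2 ln L; Akaike weights w_i = exp(-dAIC_i/2)/sum."""
    import pandas as pd

    if not fits:
        raise ValueError("no fits to compare")
    rows = [
        dict(model=f.template, k=f.n_free, loglik=f.loglik, aic=2 * f.n_free - 2 * f.loglik)
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    w = np.exp(-0.5 * df["delta_aic"].to_numpy())
    df["weight"] = w / w.sum()
    return ModelComparison(df)


@dataclass
class BootstrapResult:
    param_names: list[str]
    replicates: "pd.DataFrame"  # noqa: F821  one column per parameter
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_replicates: int
    seed: int | None


def parametric_bootstrap(
    fit: FitResult,
    template: ModelTemplate,
    n_boot: int = 100,
    n_sites: int = 10_000,
    seed: int | None = None,
    samples: SampleConfig | None = None,
    ci: float = 0.95,
    folded: bool = True,
    **fit_kwargs,
) -> BootstrapResult:
    """Percentile confidence intervals from a parametric bootstrap.

    Each replicate draws a multinomial observed SFS of ``n_sites`` sites
    from the expected SFS at the fitted estimates and re-runs the fit.
    """
    import pandas as pd

    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    model = template.build(fit.estimates)
    smp = samples
    if smp is None:
        raise ValueError("parametric_bootstrap needs the sample configuration")
    rows = []
    for _b in range(n_boot):
        sim_seed = int(rng.integers(2**31))
        # expected spectrum at the fitted point, then a finite-sites draw
        exp = expected_sfs(model, smp, fit.n_sims, seed=sim_seed, folded=folded)
        mask = exp.polymorphic_mask()
        probs = exp.data[mask]
        draws = rng.multinomial(n_sites, probs / probs.sum())
        obs_data = np.zeros_like(exp.data)
        obs_data[mask] = draws
        obs_proto = SiteFrequencySpectrum(
            exp.demes, exp.n_haploids, obs_data, folded=exp.folded
        )
        refit = fit_model(
            obs_proto,
            template,
            samples=smp,
            seed=int(rng.integers(2**31)),
            n_sims=fit.n_sims,
            **fit_kwargs,
        )
        rows.append(refit.estimates)
    reps = pd.DataFrame(rows)
    alpha = (1.0 - ci) / 2.0
    lower = {c: float(np.quantile(reps[c], alpha)) for c in reps.columns}
    upper = {c: float(np.quantile(reps[c], 1.0 - alpha)) for c in reps.columns}
    return BootstrapResult(
        param_names=list(reps.columns),
        replicates=reps,
        ci_lower=lower,
        ci_upper=upper,
        n_replicates=n_boot,
        seed=seed,
    )
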