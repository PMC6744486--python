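"""Demographic model parameterization: population trees with dated splits,
admixture pulses, and piecewise-constant deme sizes.

Time is measured in years forward from the present (larger = older) and
converted to generations internally.  Effective sizes are diploid
individuals.  The shipped four-lineage ginkgo model describes the EAST,
SOUTH, NORTH and SWEST lineages of *Ginkgo biloba*: SWEST diverged from the
EAST+SOUTH ancestor 515,780 years ago, SOUTH split from EAST 318,120 years
ago, and NORTH was founded 139,260 years ago by an admixture pulse drawing
71.55% of its ancestry from SOUTH and 28.45% from SWEST.  The most recent
common ancestral population has N_e = 50,514; descendant lineages default to
28,456 (midpoint of the inferred 24,819-32,093 range) and can be overridden
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Split",
    "AdmixturePulse",
    "SizeChange",
    "DemographicModel",
    "SampleConfig",
    "ModelValidationError",
    "build_ginkgo_model",
    "GINKGO_DEMES",
]

GINKGO_DEMES = ("EAST", "SOUTH", "NORTH", "SWEST")

#: per-site per-year mutation rate and generation time used for scaling
DEFAULT_MU_PER_YEAR = 0.67e-9
DEFAULT_GENERATION_TIME = 20.0

#: ancestral diploid N_e of the four lineages and the descendant default
#: (midpoint of the inferred 24,819-32,093 range)
GINKGO_ANCESTRAL_NE = 50_514.0
GINKGO_DESCENDANT_NE = 28_456.0

GINKGO_SPLIT_SWEST_YEARS = 515_780.0
GINKGO_SPLIT_SOUTH_YEARS = 318_120.0
GINKGO_PULSE_NORTH_YEARS = 139_260.0
GINKGO_PULSE_FRACTION_SOUTH = 0.7155
GINKGO_PULSE_FRACTION_SWEST = 0.2845


class ModelValidationError(ValueError):
    """Raised when a demographic model is internally inconsistent."""


@dataclass(frozen=True)
class Split:
    """Backwards in time, all lineages of ``child`` move into ``parent`` at
    ``time_years`` (forward in time: the child deme diverged then)."""

    time_years: float
    child: str
    parent: str


@dataclass(frozen=True)
class AdmixturePulse:
    """Instantaneous founding of ``recipient`` at ``time_years`` from
    ``sources`` (deme -> ancestry fraction; fractions sum to 1).  Backwards
    in time, each recipient lineage independently picks a source."""

    time_years: float
    recipient: str
    sources: dict[str, float]


@dataclass(frozen=True)
class SizeChange:
    """Deme ``deme`` has diploid size ``size`` for all times older than
    ``time_years`` (until any older change)."""

    time_years: float
    deme: str
    size: float


@dataclass
class DemographicModel:
    demes: tuple[str, ...]
    sizes: dict[str, float]
    splits: list[Split] = field(default_factory=list)
    admixture_pulses: list[AdmixturePulse] = field(default_factory=list)
    size_changes: list[SizeChange] = field(default_factory=list)
    mu_per_site_per_year: float = DEFAULT_MU_PER_YEAR
    generation_time_years: float = DEFAULT_GENERATION_TIME
    #: if True, mu_per_site_per_year is reinterpreted as a per-generation
    #: rate and not multiplied by the generation time
    mu_is_per_generation: bool = False

    # -- unit conversions ---------------------------------------------------

    def t_generations(self, t_years: float) -> float:
        """Exact years -> generations conversion."""
        return t_years / self.generation_time_years

    @property
    def mu_per_generation(self) -> float:
        if self.mu_is_per_generation:
            return self.mu_per_site_per_year
        return self.mu_per_site_per_year * self.generation_time_years

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self.demes) == 0:
            raise ModelValidationError("model has no demes")
        if len(set(self.demes)) != len(self.demes):
            raise ModelValidationError("duplicate deme labels")
        for d in self.demes:
            if d not in self.sizes:
                raise ModelValidationError(f"no size for deme {d!r}")
        for d, n in self.sizes.items():
            if not n > 0:
                raise ModelValidationError(f"N_e of {d!r} must be > 0, got {n}")
        exit_time: dict[str, float] = {}
        for sp in self.splits:
            if sp.time_years <= 0:
                raise ModelValidationError("split times must be > 0")
            if sp.child in exit_time:
                raise ModelValidationError(f"deme {sp.child!r} exits twice")
            exit_time[sp.child] = sp.time_years
        for p in self.admixture_pulses:
            if p.time_years <= 0:
                raise ModelValidationError("pulse times must be > 0")
            tot = sum(p.sources.values())
            if any(not (0.0 <= f <= 1.0) for f in p.sources.values()):
                raise ModelValidationError("pulse fractions must be in [0,1]")
            if abs(tot - 1.0) > 1e-9:
                raise ModelValidationError(
                    f"pulse fractions for {p.recipient!r} sum to {tot}, not 1"
                )
            if p.recipient in exit_time:
                raise ModelValidationError(f"deme {p.recipient!r} exits twice")
            exit_time[p.recipient] = p.time_years
        # every source/parent must still exist at the event time
        for sp in self.splits:
            t_parent = exit_time.get(sp.parent, float("inf"))
            if t_parent <= sp.time_years:
                raise ModelValidationError(
                    f"parent {sp.parent!r} exits before the split of {sp.child!r}"
                )
        for p in self.admixture_pulses:
            for src in p.sources:
                if exit_time.get(src, float("inf")) <= p.time_years:
                    raise ModelValidationError(
                        f"pulse source {src!r} exits before founding {p.recipient!r}"
                    )
        # exactly one root: demes that never exit
        roots = [d for d in self.demes if d not in exit_time]
        if len(roots) != 1:
            raise ModelValidationError(
                f"expected exactly one root deme, found {roots!r}: "
                "some lineages would be trapped with no ancestral path"
            )

    def with_overrides(self, **sizes: float) -> "DemographicModel":
        """Copy of the model with individual deme sizes replaced."""
        new = dict(self.sizes)
        for d, n in sizes.items():
            if d not in new:
                raise ModelValidationError(f"unknown deme {d!r}")
            new[d] = float(n)
        return replace(self, sizes=new)


@dataclass(frozen=True)
class SampleConfig:
    """Number of sampled diploid individuals per deme."""

    diploids: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.diploids.values()):
            raise ValueError("sample counts must be >= 0")
        if self.total_haploids < 2:
            raise ValueError("need at least 2 haploid lineages in total")

    def n_haploids(self, deme: str) -> int:
        return 2 * self.diploids.get(deme, 0)

    @property
    def total_haploids(self) -> int:
        return 2 * sum(self.diploids.values())


def build_ginkgo_model(
    *,
    ancestral_ne: float = GINKGO_ANCESTRAL_NE,
    descendant_ne: float = GINKGO_DESCENDANT_NE,
    t_split_swest: float = GINKGO_SPLIT_SWEST_YEARS,
    t_split_south: float = GINKGO_SPLIT_SOUTH_YEARS,
    t_pulse_north: float = GINKGO_PULSE_NORTH_YEARS,
    f_south: float = GINKGO_PULSE_FRACTION_SOUTH,
    mu_per_site_per_year: float = DEFAULT_MU_PER_YEAR,
    generation_time_years: float = DEFAULT_GENERATION_TIME,
    mu_is_per_generation: bool = False,
    **deme_ne_overrides: float,
) -> DemographicModel:
    """The four-lineage ginkgo demography (EAST, SOUTH, NORTH, SWEST).

    Two dated splits (SWEST from the EAST+SOUTH ancestor, then SOUTH from
    EAST) and one dated admixture pulse founding NORTH from SOUTH
    (fraction ``f_south``) and SWEST (``1 - f_south``).  The EAST deme
    carries the ancestral line: older than the first split it takes the
    MRCA size ``ancestral_ne``.  Splits are returned sorted oldest-first.

    Per-deme sizes can be overridden with keyword arguments named after the
    demes (e.g. ``EAST=30_000``).
    """
    sizes = {d: float(descendant_ne) for d in GINKGO_DEMES}
    for d, n in deme_ne_overrides.items():
        if d not in sizes:
            raise ModelValidationError(f"unknown deme {d!r}")
        sizes[d] = float(n)
    if not 0.0 <= f_south <= 1.0:
        raise ModelValidationError("pulse fraction must be in [0, 1]")
    model = DemographicModel(
        demes=GINKGO_DEMES,
        sizes=sizes,
        splits=[
            Split(float(t_split_swest), "SWEST", "EAST"),
            Split(float(t_split_south), "SOUTH", "EAST"),
        ],
        admixture_pulses=[
            AdmixturePulse(
                float(t_pulse_north),
                "NORTH",
                {"SOUTH": float(f_south), "SWEST": float(1.0 - f_south)},
            )
        ],
        size_changes=[SizeChange(float(t_split_swest), "EAST", float(ancestral_ne))],
        mu_per_site_per_year=mu_per_site_per_year,
        generation_time_years=generation_time_years,
        mu_is_per_generation=mu_is_per_generation,
    )
    model.splits.sort(key=lambda s: -s.time_years)
    model.validate()
    return model
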