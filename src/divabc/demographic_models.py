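"""Two-population divergence model registry, priors, and unit conversions.

Sixteen isolation-with-migration histories for a pair of sister species —
"coll" and "pied" (collared and pied flycatcher in the motivating system):
five migration scenarios (isolation, constant, recent, ancient,
recent+ancient migration) crossed with three population-size dynamics
(constant size, exponential change since the last glacial maximum,
exponential change since the split), plus a recent-unidirectional-migration
variant (RUMASC, gene flow from pied into collared only).

Parameters are drawn from uniform priors, most on a log10 scale.  Natural
units are diploid effective sizes, years (split time), generations
(migration epoch boundaries) and per-site per-generation rates.  The
ms-style simulator scaling (N/N0, T/4N0, M=4N0*m) is exposed through
explicit, exactly invertible conversions.  Migration rates follow the
backwards-in-time ms convention: m_ij is the fraction of population i made
up of migrants from population j each generation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import msprime
import numpy as np

__all__ = [
    "ScalingConvention",
    "Prior",
    "LocusRateHyperPrior",
    "ParameterDraw",
    "MigrationEpoch",
    "SizeTrajectory",
    "DemographicModel",
    "ModelDefinition",
    "MODELS",
    "MODEL_NAMES",
    "SCENARIOS",
    "default_priors",
    "draw_parameters",
    "draw_model_parameters",
    "build_model",
    "to_simulator_units",
    "from_simulator_units",
    "migration_rate_from_log10M",
    "migrants_per_generation",
]

SPECIES: Tuple[str, str] = ("coll", "pied")

#: Genome-wide mean local recombination rate (per site per generation) used
#: to normalise locus-specific rates.
GLOBAL_MEAN_RECOMBINATION = 5.3e-8


@dataclass(frozen=True)
class ScalingConvention:
    """ms-style scaling constants and the time base.

    ``n0`` is the reference effective size dividing all population sizes;
    times are measured in units of 4*n0 generations in the simulator, and
    migration is expressed as M = 4*n0*m.  ``generation_time`` converts
    user-facing years to generations.  ``lgm_generations`` is the onset of
    post-glacial size change used by the *RSC models (the last glacial
    maximum, about 21 kya at one generation per year).
    """

    n0: float = 10_000.0
    generation_time: float = 1.0
    lgm_generations: float = 21_000.0

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        if self.lgm_generations <= 0:
            raise ValueError("lgm_generations must be positive")

    def years_to_generations(self, years: float) -> float:
        return years / self.generation_time


# Parameter "unit" classes drive natural <-> simulator conversions.
# size: diploid Ne; ratio: dimensionless; migration: per-generation fraction
# (prior is on log10 of M=4*n0*m); time_years / time_generations; rate:
# per-site per-generation; shape: Gamma shape hyper-parameter.
PARAM_UNITS: Dict[str, str] = {
    "N_coll": "size",
    "N_pied": "size",
    "N_anc": "size",
    "relsize_coll": "ratio",
    "relsize_pied": "ratio",
    "m_pied_coll": "migration",
    "m_coll_pied": "migration",
    "m_anc": "migration",
    "Tm_pied_coll": "time_generations",
    "Tm_coll_pied": "time_generations",
    "Tm_anc": "time_generations",
    "T_split": "time_years",
    "mu": "rate",
    "r": "rate",
    "alpha": "shape",
}


@dataclass(frozen=True)
class Prior:
    """A uniform prior on either a linear or a log10 scale.

    ``low == high`` is permitted and denotes a fixed parameter.  For
    log10-scale priors the bounds are on the log10 of the *prior-scale*
    quantity: log10(N) for sizes, log10(x) for size ratios and log10(M)
    with M = 4*n0*m for migration rates.
    """

    name: str
    scale: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown prior scale {self.scale!r}")
        if self.low > self.high:
            raise ValueError(f"prior {self.name}: low > high")
        if self.name not in PARAM_UNITS:
            raise ValueError(f"unknown parameter name {self.name!r}")

    @property
    def unit(self) -> str:
        return PARAM_UNITS[self.name]

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value on the prior scale (before exponentiation)."""
        if self.low == self.high:
            return self.low
        return float(rng.uniform(self.low, self.high))

    def to_natural(self, u: float, scaling: ScalingConvention) -> float:
        """Map a prior-scale value to natural units."""
        if self.scale == "linear":
            return float(u)
        v = 10.0**u
        if self.unit == "migration":
            return v / (4.0 * scaling.n0)
        return v

    def to_estimation(self, value: float, scaling: ScalingConvention) -> float:
        """Map a natural-unit value back onto the prior (estimation) scale."""
        if self.scale == "linear":
            return float(value)
        if self.unit == "migration":
            return math.log10(4.0 * scaling.n0 * value)
        return math.log10(value)


@dataclass(frozen=True)
class LocusRateHyperPrior:
    """Hyper-prior for per-locus mutation and recombination rates.

    Per-locus rates are Gamma-distributed with shape ``alpha`` and rate
    ``alpha / mean`` so that the expectation equals the supplied mean.  The
    shape itself has a uniform prior (``alpha_prior``); the dataset-level
    means come from the ``mu`` and ``r`` priors of each model.
    """

    mean_mu: float = 2.0e-9
    mean_r: float = GLOBAL_MEAN_RECOMBINATION
    alpha_prior: Prior = field(
        default_factory=lambda: Prior("alpha", "linear", 1.0, 5.0)
    )

    def __post_init__(self) -> None:
        if self.mean_mu <= 0 or self.mean_r <= 0:
            raise ValueError("rate means must be positive")


@dataclass
class ParameterDraw:
    """One joint parameter draw for a model.

    ``values`` holds natural units; ``sim_values`` (when present) holds the
    ms-style simulator units produced by :func:`to_simulator_units`.
    """

    model_name: str
    values: Dict[str, float]
    sim_values: Optional[Dict[str, float]] = None

    def estimation_values(
        self, priors: Sequence[Prior], scaling: ScalingConvention
    ) -> Dict[str, float]:
        """Values on the prior scale, the scale used for ABC regression."""
        return {
            p.name: p.to_estimation(self.values[p.name], scaling)
            for p in priors
            if p.name in self.values
        }


_SIM_FACTORS = {
    "size": lambda v, s: v / s.n0,
    "ratio": lambda v, s: v,
    "migration": lambda v, s: 4.0 * s.n0 * v,
    "time_years": lambda v, s: v / s.generation_time / (4.0 * s.n0),
    "time_generations": lambda v, s: v / (4.0 * s.n0),
    "rate": lambda v, s: 4.0 * s.n0 * v,
    "shape": lambda v, s: v,
}

_NAT_FACTORS = {
    "size": lambda v, s: v * s.n0,
    "ratio": lambda v, s: v,
    "migration": lambda v, s: v / (4.0 * s.n0),
    "time_years": lambda v, s: v * s.generation_time * 4.0 * s.n0,
    "time_generations": lambda v, s: v * 4.0 * s.n0,
    "rate": lambda v, s: v / (4.0 * s.n0),
    "shape": lambda v, s: v,
}


def to_simulator_units(
    draw: ParameterDraw, scaling: ScalingConvention
) -> ParameterDraw:
    """Convert natural units to ms-style simulator units.

    Sizes become N/n0, times T/(4*n0) generations, migration rates
    M = 4*n0*m and per-site rates 4*n0*rate; ratios and shapes are
    dimensionless and pass through.
    """
    sim = {}
    for name, value in draw.values.items():
        unit = PARAM_UNITS[name]
        if unit in ("size",) and value <= 0:
            raise ValueError(f"nonpositive size {name}={value}")
        if unit in ("time_years", "time_generations", "migration", "rate") and value < 0:
            raise ValueError(f"negative {name}={value}")
        sim[name] = _SIM_FACTORS[unit](value, scaling)
    return ParameterDraw(draw.model_name, dict(draw.values), sim)


def from_simulator_units(
    draw: ParameterDraw, scaling: ScalingConvention
) -> ParameterDraw:
    """Inverse of :func:`to_simulator_units`; restores natural units."""
    if draw.sim_values is None:
        raise ValueError("draw has no simulator-unit values")
    nat = {
        name: _NAT_FACTORS[PARAM_UNITS[name]](value, scaling)
        for name, value in draw.sim_values.items()
    }
    return ParameterDraw(draw.model_name, nat, dict(draw.sim_values))


def migration_rate_from_log10M(log10_M: float, scaling: ScalingConvention) -> float:
    """Per-generation migrant fraction m from log10(M) with M = 4*n0*m."""
    return 10.0**log10_M / (4.0 * scaling.n0)


def migrants_per_generation(n_receiving: float, m: float) -> float:
    """Expected migrants per generation into the receiving population."""
    return n_receiving * m


# --------------------------------------------------------------------------
# Model registry
# --------------------------------------------------------------------------

_BASE_PARAMS = ("N_coll", "N_pied", "N_anc", "T_split", "mu", "r", "alpha")
_SIZE_PARAMS = ("relsize_coll", "relsize_pied")

_MIGRATION_PARAMS = {
    "I": (),
    "CM": ("m_pied_coll", "m_coll_pied"),
    "RM": ("m_pied_coll", "m_coll_pied", "Tm_pied_coll", "Tm_coll_pied"),
    "AM": ("m_anc", "Tm_anc"),
    "RAM": (
        "m_pied_coll",
        "m_coll_pied",
        "Tm_pied_coll",
        "Tm_coll_pied",
        "m_anc",
        "Tm_anc",
    ),
    "RUM": ("m_pied_coll", "Tm_pied_coll"),
}

SCENARIOS: Dict[str, Tuple[str, ...]] = {
    "I": ("ICS", "IRSC", "IASC"),
    "CM": ("CMCS", "CMRSC", "CMASC"),
    "RM": ("RMCS", "RMRSC", "RMASC"),
    "AM": ("AMCS", "AMRSC", "AMASC"),
    "RAM": ("RAMCS", "RAMRSC", "RAMASC"),
}


@dataclass(frozen=True)
class ModelDefinition:
    name: str
    scenario: str
    size_mode: str  # CS | RSC | ASC
    parameters: Tuple[str, ...]


def _make_registry() -> Dict[str, ModelDefinition]:
    registry = {}
    for scen, names in SCENARIOS.items():
        for name, size_mode in zip(names, ("CS", "RSC", "ASC")):
            params = _BASE_PARAMS + _MIGRATION_PARAMS[scen]
            if size_mode != "CS":
                params = params + _SIZE_PARAMS
            registry[name] = ModelDefinition(name, scen, size_mode, params)
    registry["RUMASC"] = ModelDefinition(
        "RUMASC", "RUM", "ASC", _BASE_PARAMS + _MIGRATION_PARAMS["RUM"] + _SIZE_PARAMS
    )
    return registry


MODELS: Dict[str, ModelDefinition] = _make_registry()
MODEL_NAMES: Tuple[str, ...] = tuple(MODELS)


# Default uniform prior bounds (prior scale).  The RMASC bounds are the
# study's published table; parameters of the ancient-migration scenarios
# reuse the recent-migration bounds except for the epoch boundary, which is
# placed beyond the recent-migration range so that recent+ancient models
# always have an isolation period between the two phases of gene flow.
DEFAULT_PRIOR_BOUNDS: Dict[str, Tuple[str, float, float]] = {
    "N_coll": ("log10", 4.5, 6.0),
    "N_pied": ("log10", 4.4, 5.2),
    "N_anc": ("log10", 4.5, 6.0),
    "relsize_coll": ("log10", -3.0, 3.0),
    "relsize_pied": ("log10", -1.0, 3.5),
    "m_pied_coll": ("log10", -1.5, 0.6),
    "m_coll_pied": ("log10", -4.0, 0.0),
    "m_anc": ("log10", -1.5, 0.6),
    "Tm_pied_coll": ("linear", 150.0, 25_000.0),
    "Tm_coll_pied": ("linear", 150.0, 25_000.0),
    "Tm_anc": ("linear", 25_000.0, 500_000.0),
    "T_split": ("linear", 10_000.0, 1_000_000.0),
    "mu": ("linear", 1.0e-9, 5.0e-9),
    "r": ("linear", 0.1e-8, 10.0e-8),
    "alpha": ("linear", 1.0, 5.0),
}


def default_priors(model_name: str) -> List[Prior]:
    """The default prior list for a registered model."""
    definition = _get_model(model_name)
    return [
        Prior(name, *DEFAULT_PRIOR_BOUNDS[name]) for name in definition.parameters
    ]


def _get_model(name: str) -> ModelDefinition:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}"
        ) from None


def draw_parameters(
    priors: Sequence[Prior],
    rng: np.random.Generator,
    scaling: ScalingConvention = ScalingConvention(),
    model_name: str = "",
) -> ParameterDraw:
    """Draw one joint parameter vector from uniform priors.

    Each value is uniform on its stated scale; log10-scale draws are
    exponentiated into natural units.  Deterministic under a fixed seed.
    """
    values = {p.name: p.to_natural(p.sample(rng), scaling) for p in priors}
    return ParameterDraw(model_name, values)


def draw_model_parameters(
    model_name: str,
    rng: np.random.Generator,
    scaling: ScalingConvention = ScalingConvention(),
    priors: Optional[Sequence[Prior]] = None,
    max_tries: int = 1000,
) -> ParameterDraw:
    """Draw parameters for a model, rejecting epoch-ordering violations.

    The joint prior support contains corners in which a migration or
    size-change epoch would extend beyond the split time (for example a
    split 10 ky ago with migration switched on 25 kya).  Such draws are
    rejected and redrawn, so the effective joint prior is the uniform prior
    truncated to histories whose epochs all fit inside [0, T_split].
    """
    if priors is None:
        priors = default_priors(model_name)
    definition = _get_model(model_name)
    for _ in range(max_tries):
        draw = draw_parameters(priors, rng, scaling, model_name)
        if _epochs_valid(definition, draw.values, scaling):
            return draw
    raise RuntimeError(
        f"could not draw valid parameters for {model_name} in {max_tries} tries"
    )


def _epochs_valid(
    definition: ModelDefinition, values: Dict[str, float], scaling: ScalingConvention
) -> bool:
    t_split = scaling.years_to_generations(values["T_split"])
    if definition.size_mode == "RSC" and scaling.lgm_generations >= t_split:
        return False
    for key in ("Tm_pied_coll", "Tm_coll_pied", "Tm_anc"):
        if key in values and values[key] >= t_split:
            return False
    if definition.scenario == "RAM":
        recent_stop = max(values["Tm_pied_coll"], values["Tm_coll_pied"])
        if values["Tm_anc"] <= recent_stop:
            return False
    return True


# --------------------------------------------------------------------------
# Resolved histories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MigrationEpoch:
    """Gene flow into ``receiving`` from ``source`` on [start, stop) gens ago.

    ``rate`` is the per-generation fraction of the receiving population made
    up of migrants from the source population (ms backwards convention).
    """

    receiving: str
    source: str
    rate: float
    start: float
    stop: float


@dataclass(frozen=True)
class SizeTrajectory:
    """Piecewise-exponential size history of one descendant population.

    The population has size ``current`` now and ``current * relsize`` at
    ``onset`` generations ago (and earlier, up to the split); between the
    onset and the present the size changes exponentially.  ``relsize`` None
    means constant size.
    """

    current: float
    relsize: Optional[float] = None
    onset: Optional[float] = None

    def size_at(self, t: float) -> float:
        if self.relsize is None or self.relsize == 1.0:
            return self.current
        if t >= self.onset:
            return self.current * self.relsize
        # N(t) = N_current * x^(t/onset): exponential between onset and now
        return self.current * self.relsize ** (t / self.onset)


@dataclass
class DemographicModel:
    """A fully resolved two-population divergence history.

    Times are generations before present; sizes are diploid effective
    sizes.  ``split_time`` is when the two species merge (backwards in
    time) into an ancestral population of constant size ``ancestral_size``.
    """

    name: str
    split_time: float
    trajectories: Dict[str, SizeTrajectory]
    ancestral_size: float
    migration_epochs: List[MigrationEpoch]
    scaling: ScalingConvention = field(default_factory=ScalingConvention)
    draw: Optional[ParameterDraw] = None

    def validate(self) -> None:
        if self.split_time <= 0:
            raise ValueError("split time must be positive")
        if self.ancestral_size <= 0:
            raise ValueError("ancestral size must be positive")
        for pop, traj in self.trajectories.items():
            if traj.current <= 0:
                raise ValueError(f"nonpositive current size for {pop}")
            if traj.relsize is not None:
                if traj.relsize <= 0:
                    raise ValueError(f"nonpositive relative size for {pop}")
                if traj.onset is None or not 0 < traj.onset <= self.split_time:
                    raise ValueError(
                        f"size-change onset for {pop} outside (0, split_time]"
                    )
        for ep in self.migration_epochs:
            if ep.rate < 0:
                raise ValueError("negative migration rate")
            if not 0 <= ep.start < ep.stop <= self.split_time:
                raise ValueError(
                    f"migration epoch [{ep.start}, {ep.stop}) outside "
                    f"[0, {self.split_time}]"
                )

    def size_at(self, pop: str, t: float) -> float:
        """Population size ``t`` generations ago (descendant epochs only)."""
        if t > self.split_time:
            return self.ancestral_size
        return self.trajectories[pop].size_at(t)

    def to_msprime(self) -> msprime.Demography:
        """Lower the history to an msprime Demography."""
        dem = msprime.Demography()
        for pop in SPECIES:
            traj = self.trajectories[pop]
            if traj.relsize is None or traj.relsize == 1.0:
                dem.add_population(name=pop, initial_size=traj.current)
            else:
                growth = -math.log(traj.relsize) / traj.onset
                dem.add_population(
                    name=pop, initial_size=traj.current, growth_rate=growth
                )
        dem.add_population(name="anc", initial_size=self.ancestral_size)
        for pop in SPECIES:
            traj = self.trajectories[pop]
            if traj.relsize is not None and traj.relsize != 1.0:
                if traj.onset < self.split_time:
                    # size constant at current*relsize between the onset of
                    # change and the split
                    dem.add_population_parameters_change(
                        time=traj.onset,
                        population=pop,
                        initial_size=traj.current * traj.relsize,
                        growth_rate=0.0,
                    )
        for ep in self.migration_epochs:
            if ep.start == 0:
                dem.set_migration_rate(source=ep.receiving, dest=ep.source, rate=ep.rate)
            else:
                dem.add_migration_rate_change(
                    time=ep.start, source=ep.receiving, dest=ep.source, rate=ep.rate
                )
            if ep.stop < self.split_time:
                dem.add_migration_rate_change(
                    time=ep.stop, source=ep.receiving, dest=ep.source, rate=0.0
                )
        dem.add_population_split(
            time=self.split_time, derived=list(SPECIES), ancestral="anc"
        )
        dem.sort_events()
        return dem


def build_model(
    name: str,
    draw: ParameterDraw,
    scaling: ScalingConvention = ScalingConvention(),
) -> DemographicModel:
    """Resolve a parameter draw into a concrete divergence history.

    Raises ``ValueError`` for an unknown model name, a parameter set that
    does not exactly match the model's requirements, or any epoch falling
    outside [0, split_time].
    """
    definition = _get_model(name)
    expected = set(definition.parameters)
    got = set(draw.values)
    if got != expected:
        missing = expected - got
        extra = got - expected
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if extra:
            parts.append(f"extra {sorted(extra)}")
        raise ValueError(f"parameter mismatch for {name}: " + "; ".join(parts))

    v = draw.values
    t_split = scaling.years_to_generations(v["T_split"])

    trajectories = {}
    for pop in SPECIES:
        current = v[f"N_{pop}"]
        if definition.size_mode == "CS":
            trajectories[pop] = SizeTrajectory(current)
        else:
            onset = (
                t_split
                if definition.size_mode == "ASC"
                else scaling.lgm_generations
            )
            relsize = v[f"relsize_{pop}"]
            if relsize == 1.0:
                trajectories[pop] = SizeTrajectory(current)
            else:
                trajectories[pop] = SizeTrajectory(current, relsize, onset)

    epochs: List[MigrationEpoch] = []
    scen = definition.scenario
    if scen == "CM":
        epochs.append(MigrationEpoch("coll", "pied", v["m_pied_coll"], 0.0, t_split))
        epochs.append(MigrationEpoch("pied", "coll", v["m_coll_pied"], 0.0, t_split))
    elif scen in ("RM", "RAM", "RUM"):
        epochs.append(
            MigrationEpoch("coll", "pied", v["m_pied_coll"], 0.0, v["Tm_pied_coll"])
        )
        if scen != "RUM":
            epochs.append(
                MigrationEpoch("pied", "coll", v["m_coll_pied"], 0.0, v["Tm_coll_pied"])
            )
    if scen in ("AM", "RAM"):
        # symmetric gene flow between the epoch boundary and the split
        epochs.append(
            MigrationEpoch("coll", "pied", v["m_anc"], v["Tm_anc"], t_split)
        )
        epochs.append(
            MigrationEpoch("pied", "coll", v["m_anc"], v["Tm_anc"], t_split)
        )

    model = DemographicModel(
        name=name,
        split_time=t_split,
        trajectories=trajectories,
        ancestral_size=v["N_anc"],
        migration_epochs=epochs,
        scaling=scaling,
        draw=draw,
    )
    model.validate()
    return model
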