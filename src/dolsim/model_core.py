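"""Core domain types for the cooperative-breeding simulator.

The model world is a fixed set of breeding territories, each holding at most
one dominant breeder and a queue of subordinate helpers, plus a pool of
floaters that belong to no group.  Every individual carries a haploid genome
of seven real-valued loci controlling helping effort, dispersal, task choice,
and one neutral marker used to measure within-group relatedness.

Two representations of the population are provided:

* :class:`Population` — a structure-of-arrays container used by the
  vectorized production engine (:mod:`dolsim.lifecycle`).
* :class:`Individual` / :class:`Group` — plain dataclass views used by the
  per-individual reference engine and by tests.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BenefitMode",
    "FecundityMode",
    "DispersalNorm",
    "Role",
    "Task",
    "Parameters",
    "ScenarioConfig",
    "ConfigurationError",
    "ExtinctionError",
    "Genome",
    "Individual",
    "Group",
    "Population",
    "validate_parameters",
    "init_population",
    "load_config",
    "config_lines",
    "LOCUS_NAMES",
    "ALPHA",
    "BETA",
    "BETA_0",
    "BETA_R",
    "GAMMA_0",
    "GAMMA_R",
    "NEUTRAL",
    "N_LOCI",
    "INITIAL_ALLELES",
]

# ---------------------------------------------------------------------------
# Loci

ALPHA, BETA, BETA_0, BETA_R, GAMMA_0, GAMMA_R, NEUTRAL = range(7)
N_LOCI = 7
LOCUS_NAMES = ("alpha", "beta", "beta_0", "beta_R", "gamma_0", "gamma_R", "neutral")

#: Ancestral allelic values: no helping, absolute dispersal, flat task norm.
#: The neutral locus has no meaningful initial value; it is drawn i.i.d.
#: standard normal at initialization so the relatedness regression is
#: estimable from the first generations.
INITIAL_ALLELES = (0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0)


class BenefitMode(str, enum.Enum):
    """Which fitness benefits of helping are present."""

    KS_ONLY = "KS_ONLY"   #: kin selection only: group-size survival benefit removed (x_n = 0)
    GA_ONLY = "GA_ONLY"   #: group augmentation only: philopatric newborns cross-fostered
    KS_GA = "KS_GA"       #: both (default model)


class FecundityMode(str, enum.Enum):
    """Whether breeder productivity requires balanced task allocation."""

    DOL = "DOL"           #: effective help capped near an even defense/work split
    NO_DOL = "NO_DOL"     #: total help counts regardless of task mix


class DispersalNorm(str, enum.Enum):
    """Functional form of the dispersal phenotype."""

    SCALAR = "SCALAR"         #: D = clamp(beta, 0, 1)
    RANK_NORM = "RANK_NORM"   #: logistic reaction norm of dominance, D = 1/(1+exp(beta_R*R - beta_0))


class Role(enum.IntEnum):
    BREEDER = 0
    SUBORDINATE = 1
    FLOATER = 2


class Task(enum.IntEnum):
    DEFENSE = 0
    WORK = 1
    NONE = 2


class ConfigurationError(ValueError):
    """A parameter or scenario field is out of its admissible range."""


class ExtinctionError(RuntimeError):
    """The population went extinct (all territories vacant, no floaters)."""

    def __init__(self, cycle: int):
        super().__init__(f"population extinct at cycle {cycle}")
        self.cycle = cycle


# ---------------------------------------------------------------------------
# Parameters and scenario


@dataclass(frozen=True)
class Parameters:
    """Scaling parameters of the model, fixed throughout a simulation.

    Defaults are the standard values of the model; where the model is run
    over a range (``x_h``, ``m``) the default is the midpoint used for the
    reaction-norm analyses.
    """

    y_h: float = 0.1        #: cost of work tasks on dominance value
    x_h: float = 5.0        #: cost of defensive tasks on survival
    x_n: float = 3.0        #: survival benefit of group size (0 disables group augmentation)
    x_0: float = 1.5        #: intercept of the logistic survival function
    m: float = 0.2          #: baseline mortality (environmental harshness), in [0, 1]
    f: float = 2.0          #: mean number of groups a floater samples for a vacancy
    k_m: float = 0.1        #: slack from a perfectly even task split (DoL mode)
    k_h: float = 1.0        #: effect of cumulative help on breeder fecundity
    k_0: float = 1.0        #: breeder fecundity in the absence of help
    mu: float = 0.05        #: per-locus mutation rate, in [0, 1]
    sigma_mu: float = 0.04  #: mutation step standard deviation
    N_b: int = 5000         #: number of breeding territories
    n_cycles: int = 200_000  #: run length in breeding cycles
    n_replicates: int = 20   #: replicate count for grid runs

    def replace(self, **kw) -> "Parameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario switches selecting the model variant."""

    benefit_mode: BenefitMode = BenefitMode.KS_GA
    fecundity_mode: FecundityMode = FecundityMode.DOL
    dispersal_norm: DispersalNorm = DispersalNorm.SCALAR
    seed: int = 0

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


def validate_parameters(params: Parameters, scenario: ScenarioConfig) -> tuple[Parameters, ScenarioConfig]:
    """Validate a configuration and apply scenario-forced overrides.

    Returns a possibly modified copy: the kin-selection-only scenario removes
    the survival benefit of group size, so ``x_n`` is forced to 0 there.

    Raises
    ------
    ConfigurationError
        Naming the offending field, if any value is out of range.
    """
    p = params

    def _bad(name, msg):
        raise ConfigurationError(f"{name}: {msg} (got {getattr(p, name)!r})")

    if not (0.0 <= p.m <= 1.0):
        _bad("m", "baseline mortality must lie in [0, 1]")
    if not (0.0 <= p.mu <= 1.0):
        _bad("mu", "mutation rate must lie in [0, 1]")
    if p.sigma_mu < 0:
        _bad("sigma_mu", "mutation step SD must be >= 0")
    if p.N_b < 1:
        _bad("N_b", "need at least one breeding territory")
    if p.k_m < 0:
        _bad("k_m", "task-split slack must be >= 0")
    if p.f < 0:
        _bad("f", "floater sampling rate must be >= 0")
    if p.n_cycles < 1:
        _bad("n_cycles", "run length must be >= 1")
    if p.n_replicates < 1:
        _bad("n_replicates", "replicate count must be >= 1")
    for name in ("y_h", "x_h", "x_n", "x_0", "k_h", "k_0"):
        if not np.isfinite(getattr(p, name)):
            _bad(name, "must be finite")
    if scenario.benefit_mode is BenefitMode.KS_ONLY and p.x_n != 0.0:
        p = p.replace(x_n=0.0)
    return p, scenario


# ---------------------------------------------------------------------------
# Object views (reference engine, tests)


@dataclass
class Genome:
    """Haploid genome of seven real-valued loci.

    All loci are unbounded, with phenotypes clamped at expression, except
    the dispersal locus ``beta``: it lives directly on the probability
    scale and is truncated to [0, 1] at inheritance.
    """

    alpha: float = INITIAL_ALLELES[ALPHA]
    beta: float = INITIAL_ALLELES[BETA]
    beta_0: float = INITIAL_ALLELES[BETA_0]
    beta_R: float = INITIAL_ALLELES[BETA_R]
    gamma_0: float = INITIAL_ALLELES[GAMMA_0]
    gamma_R: float = INITIAL_ALLELES[GAMMA_R]
    neutral: float = INITIAL_ALLELES[NEUTRAL]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta, self.beta_0, self.beta_R,
             self.gamma_0, self.gamma_R, self.neutral]
        )

    @classmethod
    def from_array(cls, a) -> "Genome":
        return cls(*(float(x) for x in a))


@dataclass
class Individual:
    genome: Genome
    age: int = 1
    role: Role = Role.SUBORDINATE
    group_id: int | None = None
    task: Task = Task.NONE


@dataclass
class Group:
    territory_id: int
    breeder: Individual | None = None
    subordinates: list[Individual] = field(default_factory=list)
    prev_sum_H_defense: float = 0.0
    prev_sum_H_work: float = 0.0

    @property
    def size(self) -> int:
        return (1 if self.breeder is not None else 0) + len(self.subordinates)


# ---------------------------------------------------------------------------
# Structure-of-arrays population


class Population:
    """All living individuals plus per-territory help bookkeeping.

    Individuals live in flat parallel arrays; the ``group`` column is the
    territory index for breeders and subordinates and ``-1`` for floaters.
    ``prev_sum_*`` hold the cumulative help of the previous cycle only (they
    are overwritten, never accumulated across cycles).
    """

    __slots__ = ("genes", "age", "role", "group", "task",
                 "prev_sum_def", "prev_sum_work", "N_b", "cycle")

    def __init__(self, N_b: int):
        self.N_b = int(N_b)
        self.genes = np.empty((0, N_LOCI), dtype=np.float64)
        self.age = np.empty(0, dtype=np.int64)
        self.role = np.empty(0, dtype=np.int8)
        self.group = np.empty(0, dtype=np.int64)
        self.task = np.empty(0, dtype=np.int8)
        self.prev_sum_def = np.zeros(N_b, dtype=np.float64)
        self.prev_sum_work = np.zeros(N_b, dtype=np.float64)
        self.cycle = 0

    # -- sizes -------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.age.shape[0]

    @property
    def n_floaters(self) -> int:
        return int(np.count_nonzero(self.role == Role.FLOATER))

    def breeder_of(self) -> np.ndarray:
        """Index of each territory's breeder in the flat arrays, -1 if vacant."""
        out = np.full(self.N_b, -1, dtype=np.int64)
        mask = self.role == Role.BREEDER
        out[self.group[mask]] = np.nonzero(mask)[0]
        return out

    def group_sizes(self) -> np.ndarray:
        """Breeder + subordinates per territory (floaters count nowhere)."""
        members = self.group[self.role != Role.FLOATER]
        return np.bincount(members, minlength=self.N_b)

    # -- mutation ----------------------------------------------------------

    def append(self, genes, age, role, group, task) -> None:
        self.genes = np.concatenate([self.genes, genes])
        self.age = np.concatenate([self.age, age])
        self.role = np.concatenate([self.role, role])
        self.group = np.concatenate([self.group, group])
        self.task = np.concatenate([self.task, task])

    def keep(self, mask: np.ndarray) -> None:
        """Drop individuals where ``mask`` is False (stable order)."""
        self.genes = self.genes[mask]
        self.age = self.age[mask]
        self.role = self.role[mask]
        self.group = self.group[mask]
        self.task = self.task[mask]

    def copy(self) -> "Population":
        out = Population(self.N_b)
        out.genes = self.genes.copy()
        out.age = self.age.copy()
        out.role = self.role.copy()
        out.group = self.group.copy()
        out.task = self.task.copy()
        out.prev_sum_def = self.prev_sum_def.copy()
        out.prev_sum_work = self.prev_sum_work.copy()
        out.cycle = self.cycle
        return out

    # -- conversions -------------------------------------------------------

    def to_individuals(self) -> tuple[list[Group], list[Individual]]:
        groups = [Group(territory_id=g,
                        prev_sum_H_defense=float(self.prev_sum_def[g]),
                        prev_sum_H_work=float(self.prev_sum_work[g]))
                  for g in range(self.N_b)]
        floaters: list[Individual] = []
        for i in range(self.n):
            ind = Individual(genome=Genome.from_array(self.genes[i]),
                             age=int(self.age[i]), role=Role(self.role[i]),
                             group_id=int(self.group[i]) if self.group[i] >= 0 else None,
                             task=Task(self.task[i]))
            if ind.role is Role.FLOATER:
                floaters.append(ind)
            elif ind.role is Role.BREEDER:
                groups[ind.group_id].breeder = ind
            else:
                groups[ind.group_id].subordinates.append(ind)
        return groups, floaters

    def canonical(self) -> np.ndarray:
        """A sorted structured view for order-insensitive state comparison."""
        rec = np.empty(self.n, dtype=[("role", "i1"), ("group", "i8"),
                                      ("age", "i8"), ("task", "i1"),
                                      ("genes", "f8", (N_LOCI,))])
        rec["role"] = self.role
        rec["group"] = self.group
        rec["age"] = self.age
        rec["task"] = self.task
        rec["genes"] = self.genes
        order = np.lexsort(tuple(self.genes[:, k] for k in range(N_LOCI))
                           + (self.age, self.task, self.group, self.role))
        return rec[order]


def init_population(params: Parameters, rng: np.random.Generator) -> Population:
    """Founding population: one breeder per territory, age 1, ancestral alleles.

    The neutral locus is drawn i.i.d. standard normal (territory index order)
    so that breeder-helper regressions have variance to work with from the
    start; every other locus starts at its ancestral value.
    """
    pop = Population(params.N_b)
    n = params.N_b
    genes = np.tile(np.asarray(INITIAL_ALLELES, dtype=np.float64), (n, 1))
    genes[:, NEUTRAL] = rng.normal(0.0, 1.0, size=n)
    pop.append(genes,
               np.ones(n, dtype=np.int64),
               np.full(n, Role.BREEDER, dtype=np.int8),
               np.arange(n, dtype=np.int64),
               np.full(n, Task.NONE, dtype=np.int8))
    return pop


# ---------------------------------------------------------------------------
# Flat key-value configuration files

_PARAM_FLOAT = ("y_h", "x_h", "x_n", "x_0", "m", "f", "k_m", "k_h", "k_0",
                "mu", "sigma_mu")
_PARAM_INT = ("N_b", "n_cycles", "n_replicates")
_SCENARIO_KEYS = ("benefit_mode", "fecundity_mode", "dispersal_norm", "seed")


def load_config(path) -> tuple[Parameters, ScenarioConfig]:
    """Read a flat ``key = value`` configuration file.

    Keys use the standard model symbols spelled out (``x_h``, ``k_m``,
    ``benefit_mode``...).  Lines starting with ``#`` and blank lines are
    ignored.  Unknown keys are an error.
    """
    pkw: dict = {}
    skw: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _PARAM_FLOAT:
            pkw[key] = float(value)
        elif key in _PARAM_INT:
            pkw[key] = int(value)
        elif key == "seed":
            skw[key] = int(value)
        elif key == "benefit_mode":
            skw[key] = BenefitMode(value)
        elif key == "fecundity_mode":
            skw[key] = FecundityMode(value)
        elif key == "dispersal_norm":
            skw[key] = DispersalNorm(value)
        else:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
    return Parameters(**pkw), ScenarioConfig(**skw)


def config_lines(params: Parameters, scenario: ScenarioConfig) -> list[str]:
    """The configuration as ``key = value`` lines, echoed into output headers."""
    lines = [f"{k} = {getattr(params, k)!r}" for k in _PARAM_FLOAT]
    lines += [f"{k} = {getattr(params, k)}" for k in _PARAM_INT]
    lines += [f"{k} = {getattr(scenario, k).value}"
              for k in ("benefit_mode", "fecundity_mode", "dispersal_norm")]
    lines.append(f"seed = {scenario.seed}")
    return lines
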