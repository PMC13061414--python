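"""One breeding cycle of the simulation engine.

A cycle applies, in order: reproduction, dispersal (with the optional
cross-foster manipulation of the group-augmentation-only scenario), task
choice and help accumulation, survival, breeder replacement, and aging.

Draw-order contract
-------------------
Fixing the seed fixes the run.  Each phase consumes randomness in a
documented order (individuals in flat-array index order, territories in
increasing index order), so the vectorized engine and the per-individual
reference engine (:mod:`dolsim.reference`) produce bit-identical states
from the same generator state:

1. reproduction: one Poisson draw per occupied territory (territory
   order); then mutation uniforms, one per (offspring, locus) row-major
   (offspring ordered by territory, then birth order); then one mutation
   normal per mutating locus, in the same row-major order.
2. dispersal: one uniform per subordinate (index order; newborns sit at
   the end of the arrays in birth order); then one uniform per leaver
   (index order) for the settle-vs-float decision; then one territory
   index per settling leaver (index order); then, in the GA-only
   scenario, one permutation of the philopatric newborns.
3. task choice: one uniform per subordinate (index order).
4. survival: one uniform per individual (index order).
5. breeder replacement: one Poisson bidder count per vacant territory
   (territory order); one permutation of the floater pool; one Gumbel
   variate per lottery candidate (vacancies in territory order; within a
   vacancy, the group's subordinates in index order, then its bidders in
   assignment order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior_genetics import dominance_value, mutate
from .model_core import (
    ALPHA, BETA, BETA_0, BETA_R, GAMMA_0, GAMMA_R,
    BenefitMode, DispersalNorm, FecundityMode, Parameters, Population, Role,
    ScenarioConfig, Task,
)

__all__ = [
    "CycleTally",
    "effective_group_help",
    "fecundity_mean",
    "reproduce",
    "dispersal_step",
    "help_step",
    "survival_step",
    "survival_probability",
    "sample_bidders",
    "fill_vacancies",
    "step_cycle",
]

_ROLES = (Role.BREEDER, Role.SUBORDINATE, Role.FLOATER)

# plain ints for hot loops (IntEnum attribute access is surprisingly costly)
_BREEDER, _SUB, _FLOATER = int(Role.BREEDER), int(Role.SUBORDINATE), int(Role.FLOATER)
_DEFENSE, _WORK, _NONE = int(Task.DEFENSE), int(Task.WORK), int(Task.NONE)


@dataclass
class CycleTally:
    """Per-cycle bookkeeping needed for summaries."""

    n_newborns: int = 0
    at_risk: dict = field(default_factory=lambda: {r: 0 for r in _ROLES})
    survived: dict = field(default_factory=lambda: {r: 0 for r in _ROLES})

    @property
    def survival_overall(self) -> float:
        n = sum(self.at_risk.values())
        return sum(self.survived.values()) / n if n else float("nan")

    def survival_of(self, role: Role) -> float:
        n = self.at_risk[role]
        return self.survived[role] / n if n else float("nan")


# ---------------------------------------------------------------------------
# Fecundity


def effective_group_help(sum_H_def, sum_H_work, k_m: float,
                         fecundity_mode: FecundityMode):
    """Cumulative group help that actually counts toward fecundity.

    In NO_DOL mode both sums pass through unchanged.  In DOL mode the
    breeder's productivity is maximized by a balanced task split: each sum
    is truncated at H_max = (sum_def + sum_work)/2 + k_m, so lopsided
    effort is partly wasted.
    """
    sd = np.asarray(sum_H_def, dtype=np.float64)
    sw = np.asarray(sum_H_work, dtype=np.float64)
    if fecundity_mode is FecundityMode.NO_DOL:
        return sd, sw
    h_max = (sd + sw) / 2.0 + k_m
    return np.minimum(sd, h_max), np.minimum(sw, h_max)


def fecundity_mean(k_0: float, k_h: float, eff_def, eff_work):
    """Mean offspring number K = k_0 + k_h * S / (1 + S), S = total help.

    Help raises fecundity with diminishing returns; K saturates at
    k_0 + k_h.
    """
    s = np.asarray(eff_def, dtype=np.float64) + np.asarray(eff_work, dtype=np.float64)
    return k_0 + k_h * s / (1.0 + s)


# ---------------------------------------------------------------------------
# Phase 1: reproduction


def reproduce(pop: Population, params: Parameters, scenario: ScenarioConfig,
              rng: np.random.Generator) -> int:
    """Asexual reproduction by every living breeder.

    Offspring counts are Poisson with mean K computed from the *previous*
    cycle's cumulative help; each offspring inherits its breeder's genome
    through mutation and starts as an age-1 subordinate of the natal group
    (its own dispersal decision follows in phase 2).  Vacant territories
    produce nothing.  Returns the number of newborns.
    """
    b_idx = pop.breeder_of()
    occ = np.nonzero(b_idx >= 0)[0]
    if occ.size == 0:
        return 0
    eff_def, eff_work = effective_group_help(
        pop.prev_sum_def[occ], pop.prev_sum_work[occ], params.k_m,
        scenario.fecundity_mode)
    K = fecundity_mean(params.k_0, params.k_h, eff_def, eff_work)
    n_off = rng.poisson(K)
    total = int(n_off.sum())
    if total == 0:
        # keep the mutation-phase stream consumption at zero draws
        return 0
    parents = np.repeat(b_idx[occ], n_off)
    child_genes = mutate(pop.genes[parents], params.mu, params.sigma_mu, rng)
    # the dispersal locus lives on the probability scale and is hard-bounded:
    # mutation steps crossing [0, 1] are truncated at inheritance
    np.clip(child_genes[:, BETA], 0.0, 1.0, out=child_genes[:, BETA])
    pop.append(child_genes,
               np.ones(total, dtype=np.int64),
               np.full(total, Role.SUBORDINATE, dtype=np.int8),
               np.repeat(occ, n_off).astype(np.int64),
               np.full(total, Task.NONE, dtype=np.int8))
    return total


# ---------------------------------------------------------------------------
# Phase 2: dispersal


def dispersal_step(pop: Population, params: Parameters,
                   scenario: ScenarioConfig, rng: np.random.Generator) -> None:
    """Dispersal of subordinates and settlement of this cycle's dispersers.

    Every subordinate (newborns included) leaves its group with
    probability D.  Each leaver then decides once, with the same genetic
    predisposition, between migrating into a uniformly random territory
    as an immigrant subordinate (probability 1 - D) or floating.
    Standing floaters from earlier cycles keep waiting for a breeding
    vacancy; they re-enter groups only by winning one.  In the GA-only
    scenario the philopatric newborns are finally shuffled among their
    natal territories, severing the kin-structure signal while leaving
    group sizes untouched.
    """
    newborn = (pop.age == 1) & (pop.role == _SUB)
    left = np.zeros(pop.n, dtype=bool)

    def _propensity(idx: np.ndarray) -> np.ndarray:
        # column gathers; equals dispersal_propensity on pop.genes[idx]
        if scenario.dispersal_norm is DispersalNorm.SCALAR:
            return np.clip(pop.genes[idx, BETA], 0.0, 1.0)
        R = pop.age[idx].astype(np.float64)  # pre-work dominance
        return 1.0 / (1.0 + np.exp(pop.genes[idx, BETA_R] * R
                                   - pop.genes[idx, BETA_0]))

    subs = np.nonzero(pop.role == _SUB)[0]
    if subs.size:
        leave = rng.random(subs.size) < _propensity(subs)
        goers = subs[leave]
        left[goers] = True
        pop.role[goers] = _FLOATER
        pop.group[goers] = -1

    if subs.size and goers.size:
        join = rng.random(goers.size) < 1.0 - _propensity(goers)
        joiners = goers[join]
        targets = rng.integers(0, pop.N_b, size=joiners.size)
        pop.role[joiners] = _SUB
        pop.group[joiners] = targets

    if scenario.benefit_mode is BenefitMode.GA_ONLY:
        philo = np.nonzero(newborn & ~left & (pop.role == _SUB))[0]
        if philo.size:
            perm = rng.permutation(philo.size)
            pop.group[philo] = pop.group[philo][perm]


# ---------------------------------------------------------------------------
# Phase 3: task choice and help accumulation


def help_step(pop: Population, params: Parameters,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Task choice and accumulation of this cycle's group help sums.

    Each subordinate draws the defensive task with probability T evaluated
    at its pre-work dominance (R = age), else the work task; its full
    lifetime help H accrues to the group's sum for that task.  Breeders
    and floaters perform no task and contribute nothing.  Returns the
    per-territory (defense, work) sums for this cycle.
    """
    pop.task[:] = _NONE
    subs = np.nonzero(pop.role == _SUB)[0]
    sum_def = np.zeros(pop.N_b)
    sum_work = np.zeros(pop.N_b)
    if subs.size == 0:
        return sum_def, sum_work
    # inline task_probability / express_help via column gathers and
    # in-place chaining (hot path); identical arithmetic to the module
    # functions in behavior_genetics
    t = pop.genes[subs, GAMMA_R]
    t *= pop.age[subs]
    t -= pop.genes[subs, GAMMA_0]
    np.exp(t, out=t)
    t += 1.0
    np.reciprocal(t, out=t)          # T, the defense probability
    defend = rng.random(subs.size) < t
    tasks = np.full(subs.size, _WORK, dtype=np.int8)
    tasks[defend] = _DEFENSE
    pop.task[subs] = tasks
    H = np.maximum(0.0, pop.genes[subs, ALPHA])
    g = pop.group[subs]
    w_def = np.where(defend, H, 0.0)
    sum_def = np.bincount(g, weights=w_def, minlength=pop.N_b)
    sum_work = np.bincount(g, weights=H - w_def, minlength=pop.N_b)
    return sum_def, sum_work


# ---------------------------------------------------------------------------
# Phase 4: survival


def survival_probability(pop: Population, params: Parameters) -> np.ndarray:
    """Per-individual survival probability for the current cycle.

    Logistic in social state, scaled by the environment: breeders get the
    group-size benefit, subordinates additionally pay the defense cost on
    this cycle's helping effort, and floaters get neither benefit nor
    cost.  All probabilities are bounded above by 1 - m.
    """
    z = np.full(pop.n, params.x_0)
    if params.x_n != 0.0:
        sizes = pop.group_sizes()
        grouped = pop.role != _FLOATER
        z[grouped] += params.x_n * sizes[pop.group[grouped]]
    if params.x_h != 0.0:
        defending = pop.task == _DEFENSE
        if np.any(defending):
            z[defending] -= params.x_h * np.maximum(0.0, pop.genes[defending, ALPHA])
    np.negative(z, out=z)
    np.exp(z, out=z)
    z += 1.0
    np.divide(1.0 - params.m, z, out=z)
    return z


def survival_step(pop: Population, params: Parameters,
                  rng: np.random.Generator) -> CycleTally:
    """Stochastic survival; the dead are removed from the population."""
    s = survival_probability(pop, params)
    alive = rng.random(pop.n) < s
    tally = CycleTally()
    at_risk = np.bincount(pop.role, minlength=3)
    survived = np.bincount(pop.role[alive], minlength=3)
    for role in _ROLES:
        tally.at_risk[role] = int(at_risk[role])
        tally.survived[role] = int(survived[role])
    pop.keep(alive)
    return tally


# ---------------------------------------------------------------------------
# Phase 5: breeder replacement


def sample_bidders(n_vacancies: int, N_f: int, N_b: int, f: float,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Floater candidate sets for each vacancy.

    Each vacancy draws Poisson(f * N_f / N_b) bidders; each floater bids
    for at most one vacancy per cycle, so draws are taken without
    replacement from a single permutation of the pool and counts are
    truncated (in territory order) once the pool is exhausted.  Returns,
    per vacancy, positions into the floater pool (pool index order as
    passed in).
    """
    if n_vacancies == 0:
        return []
    counts, chosen = _sample_bidders_flat(n_vacancies, N_f, N_b, f, rng)
    ends = np.cumsum(counts)
    starts = ends - counts
    return [chosen[s:e] for s, e in zip(starts, ends)]


def _sample_bidders_flat(n_vacancies: int, N_f: int, N_b: int, f: float,
                         rng: np.random.Generator):
    """Bidder counts per vacancy plus the chosen pool positions, flat."""
    lam = f * N_f / N_b if N_b else 0.0
    counts = rng.poisson(lam, size=n_vacancies)
    ends = np.minimum(np.cumsum(counts), N_f)
    counts = np.diff(ends, prepend=0)
    perm = rng.permutation(N_f)
    return counts, perm[:ends[-1] if n_vacancies else 0]


def fill_vacancies(pop: Population, params: Parameters,
                   rng: np.random.Generator) -> None:
    """Lottery for every territory without a living breeder.

    Candidates are the territory's surviving subordinates plus that
    vacancy's sampled floater bidders.  The winner is drawn with
    probability proportional to dominance R (this cycle's work cost
    applied); if every candidate has R = 0 the lottery is uniform.  A
    vacancy with no candidates stays vacant.  Weighted sampling is
    realized as Gumbel-max over log-weights, which keeps the draw order
    per-candidate and vectorizable.
    """
    b_idx = pop.breeder_of()
    vac = np.nonzero(b_idx < 0)[0]
    if vac.size == 0:
        return
    floaters = np.nonzero(pop.role == _FLOATER)[0]
    counts, chosen = _sample_bidders_flat(vac.size, floaters.size, pop.N_b,
                                          params.f, rng)

    vac_ord = np.full(pop.N_b, -1, dtype=np.int64)
    vac_ord[vac] = np.arange(vac.size)

    subs = np.nonzero(pop.role == _SUB)[0]
    sub_cand = subs[vac_ord[pop.group[subs]] >= 0]
    bid_cand = floaters[chosen]
    bid_vac = np.repeat(np.arange(vac.size), counts)

    cand = np.concatenate([sub_cand, bid_cand])
    if cand.size == 0:
        rng.gumbel(size=0)
        return
    cand_vac = np.concatenate([vac_ord[pop.group[sub_cand]], bid_vac])
    # contract order: per vacancy, subordinates (index order) then bidders
    seq = np.concatenate([sub_cand, pop.n + np.arange(bid_cand.size)])
    order = np.lexsort((seq, cand_vac))
    cand, cand_vac = cand[order], cand_vac[order]

    H = np.maximum(0.0, pop.genes[cand, ALPHA])
    H_work = np.where(pop.task[cand] == _WORK, H, 0.0)
    R = dominance_value(pop.age[cand], params.y_h, H_work)
    sum_R = np.bincount(cand_vac, weights=R, minlength=vac.size)
    w = np.where(sum_R[cand_vac] > 0.0, R, 1.0)
    with np.errstate(divide="ignore"):
        score = np.log(w) + rng.gumbel(size=cand.size)
    # first-of-segment after sorting by (vacancy, descending score)
    pick = np.lexsort((-score, cand_vac))
    first = np.concatenate([[True], cand_vac[pick][1:] != cand_vac[pick][:-1]])
    winners = cand[pick[first]]
    win_vac = vac[cand_vac[pick[first]]]
    pop.role[winners] = _BREEDER
    pop.group[winners] = win_vac


# ---------------------------------------------------------------------------
# Full cycle


def step_cycle(pop: Population, params: Parameters, scenario: ScenarioConfig,
               rng: np.random.Generator) -> CycleTally:
    """Advance the population by one breeding cycle (phases 1-5 + aging)."""
    tally = CycleTally()
    tally.n_newborns = reproduce(pop, params, scenario, rng)
    dispersal_step(pop, params, scenario, rng)
    sum_def, sum_work = help_step(pop, params, rng)
    t = survival_step(pop, params, rng)
    tally.at_risk, tally.survived = t.at_risk, t.survived
    fill_vacancies(pop, params, rng)
    pop.age += 1
    pop.prev_sum_def = sum_def
    pop.prev_sum_work = sum_work
    pop.cycle += 1
    return tally
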