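"""Unoptimized per-individual reference engine.

This module re-implements one breeding cycle with plain Python loops over
individuals and territories, independently of the vectorized engine in
:mod:`dolsim.lifecycle`.  It follows the same documented draw-order
contract (see that module's docstring), so given the same generator state
the two engines must produce bit-identical population states — a strong
cross-check that the vectorized bookkeeping (bincounts, segment argmax,
compaction) implements the per-individual rules exactly.

Only used by tests; far too slow for production runs.
"""

from __future__ import annotations

import math

import numpy as np

from .model_core import (
    ALPHA, BETA, BETA_0, BETA_R, GAMMA_0, GAMMA_R, N_LOCI,
    BenefitMode, DispersalNorm, FecundityMode, Parameters, Population, Role,
    ScenarioConfig, Task,
)

__all__ = ["step_cycle_reference"]


def _help(alpha: float) -> float:
    return max(0.0, alpha)


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(z))


def step_cycle_reference(pop: Population, params: Parameters,
                         scenario: ScenarioConfig,
                         rng: np.random.Generator) -> None:
    """Advance ``pop`` by one cycle using scalar per-individual logic."""
    p, s = params, scenario

    # ---- phase 1: reproduction -------------------------------------------
    breeder_of = {}
    for i in range(pop.n):
        if pop.role[i] == Role.BREEDER:
            breeder_of[int(pop.group[i])] = i
    occupied = sorted(breeder_of)
    counts = []
    for g in occupied:
        sd, sw = float(pop.prev_sum_def[g]), float(pop.prev_sum_work[g])
        if s.fecundity_mode is FecundityMode.DOL:
            h_max = (sd + sw) / 2.0 + p.k_m
            sd, sw = min(sd, h_max), min(sw, h_max)
        tot = sd + sw
        K = p.k_0 + p.k_h * tot / (1.0 + tot)
        counts.append(int(rng.poisson(K)))
    newborn_genes, newborn_group = [], []
    for g, c in zip(occupied, counts):
        for _ in range(c):
            newborn_genes.append(pop.genes[breeder_of[g]].copy())
            newborn_group.append(g)
    if newborn_genes:
        u = [[rng.random() for _ in range(N_LOCI)] for _ in newborn_genes]
        for k, genes in enumerate(newborn_genes):
            for locus in range(N_LOCI):
                if u[k][locus] < p.mu:
                    genes[locus] += rng.normal(0.0, p.sigma_mu)
        for genes in newborn_genes:
            genes[BETA] = min(1.0, max(0.0, genes[BETA]))  # bounded locus
        pop.append(np.array(newborn_genes),
                   np.ones(len(newborn_genes), dtype=np.int64),
                   np.full(len(newborn_genes), Role.SUBORDINATE, dtype=np.int8),
                   np.array(newborn_group, dtype=np.int64),
                   np.full(len(newborn_genes), Task.NONE, dtype=np.int8))

    # ---- phase 2: dispersal ----------------------------------------------
    def _dispersal(i: int) -> float:
        if s.dispersal_norm is DispersalNorm.SCALAR:
            return min(1.0, max(0.0, float(pop.genes[i, BETA])))
        r = float(pop.age[i])
        return _logistic(float(pop.genes[i, BETA_R]) * r - float(pop.genes[i, BETA_0]))

    newborn = [(int(pop.age[i]) == 1 and pop.role[i] == Role.SUBORDINATE)
               for i in range(pop.n)]
    left = [False] * pop.n
    for i in range(pop.n):
        if pop.role[i] == Role.SUBORDINATE:
            if rng.random() < _dispersal(i):
                left[i] = True
                pop.role[i] = Role.FLOATER
                pop.group[i] = -1
    joiners = []
    for i in range(pop.n):
        if left[i]:  # only this cycle's dispersers may settle
            if rng.random() < 1.0 - _dispersal(i):
                joiners.append(i)
    for i in joiners:
        pop.role[i] = Role.SUBORDINATE
        pop.group[i] = int(rng.integers(0, pop.N_b))
    if s.benefit_mode is BenefitMode.GA_ONLY:
        philo = [i for i in range(pop.n)
                 if newborn[i] and not left[i] and pop.role[i] == Role.SUBORDINATE]
        if philo:
            perm = rng.permutation(len(philo))
            labels = [int(pop.group[i]) for i in philo]
            for k, i in enumerate(philo):
                pop.group[i] = labels[perm[k]]

    # ---- phase 3: task choice and help -----------------------------------
    sum_def = [0.0] * pop.N_b
    sum_work = [0.0] * pop.N_b
    pop.task[:] = Task.NONE
    for i in range(pop.n):
        if pop.role[i] != Role.SUBORDINATE:
            continue
        T = _logistic(float(pop.genes[i, GAMMA_R]) * float(pop.age[i])
                      - float(pop.genes[i, GAMMA_0]))
        if rng.random() < T:
            pop.task[i] = Task.DEFENSE
            sum_def[int(pop.group[i])] += _help(float(pop.genes[i, ALPHA]))
        else:
            pop.task[i] = Task.WORK
            sum_work[int(pop.group[i])] += _help(float(pop.genes[i, ALPHA]))

    # ---- phase 4: survival -----------------------------------------------
    size = [0] * pop.N_b
    for i in range(pop.n):
        if pop.role[i] != Role.FLOATER:
            size[int(pop.group[i])] += 1
    alive = np.zeros(pop.n, dtype=bool)
    for i in range(pop.n):
        z = p.x_0
        if pop.role[i] != Role.FLOATER:
            z += p.x_n * size[int(pop.group[i])]
        if pop.task[i] == Task.DEFENSE:
            z -= p.x_h * _help(float(pop.genes[i, ALPHA]))
        surv = (1.0 - p.m) * _logistic(-z)
        alive[i] = rng.random() < surv
    pop.keep(alive)

    # ---- phase 5: breeder replacement ------------------------------------
    has_breeder = [False] * pop.N_b
    for i in range(pop.n):
        if pop.role[i] == Role.BREEDER:
            has_breeder[int(pop.group[i])] = True
    vacancies = [g for g in range(pop.N_b) if not has_breeder[g]]
    if vacancies:
        floaters = [i for i in range(pop.n) if pop.role[i] == Role.FLOATER]
        lam = p.f * len(floaters) / pop.N_b
        counts = [int(rng.poisson(lam)) for _ in vacancies]
        # truncate in territory order once the pool runs dry
        cum = 0
        for k in range(len(counts)):
            counts[k] = min(counts[k], len(floaters) - cum)
            cum += counts[k]
        perm = rng.permutation(len(floaters))
        pos = 0
        cand_of = {}
        for k, g in enumerate(vacancies):
            bids = [floaters[perm[j]] for j in range(pos, pos + counts[k])]
            pos += counts[k]
            subs = [i for i in range(pop.n)
                    if pop.role[i] == Role.SUBORDINATE and pop.group[i] == g]
            cand_of[g] = subs + bids
        for g in vacancies:
            cands = cand_of[g]
            if not cands:
                continue
            R = []
            for i in cands:
                h_work = _help(float(pop.genes[i, ALPHA])) if pop.task[i] == Task.WORK else 0.0
                R.append(max(0.0, float(pop.age[i]) - p.y_h * h_work))
            uniform = sum(R) <= 0.0
            best, best_score = None, -math.inf
            for i, r in zip(cands, R):
                w = 1.0 if uniform else r
                lw = math.log(w) if w > 0 else -math.inf
                score = lw + rng.gumbel()
                if score > best_score:
                    best, best_score = i, score
            pop.role[best] = Role.BREEDER
            pop.group[best] = g

    # ---- aging and bookkeeping -------------------------------------------
    pop.age += 1
    pop.prev_sum_def = np.array(sum_def)
    pop.prev_sum_work = np.array(sum_work)
    pop.cycle += 1
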