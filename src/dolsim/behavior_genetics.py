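"""Phenotype expression, inheritance with mutation, and relatedness.

All functions are vectorized: scalar or array arguments are accepted and
broadcast.  Allelic values are unbounded reals; clamping to the admissible
phenotype range happens here, at expression time, never at the gene.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    ALPHA, BETA, BETA_0, BETA_R, GAMMA_0, GAMMA_R,
    DispersalNorm, Genome,
)

__all__ = [
    "express_help",
    "dispersal_propensity",
    "task_probability",
    "dominance_value",
    "mutate",
    "estimate_relatedness",
]


def _genes(genome) -> np.ndarray:
    if isinstance(genome, Genome):
        return genome.as_array()[None, :]
    return np.atleast_2d(np.asarray(genome, dtype=np.float64))


def express_help(genome) -> np.ndarray | float:
    """Lifetime helping effort H = max(0, alpha).

    The amount of help is fixed at birth; only the *kind* of task performed
    varies over life (through :func:`task_probability`).
    """
    scalar = isinstance(genome, Genome) or np.ndim(genome) == 1
    g = _genes(genome)
    h = np.maximum(0.0, g[:, ALPHA])
    return float(h[0]) if scalar else h


def dispersal_propensity(genome, R=0.0, variant: DispersalNorm = DispersalNorm.SCALAR):
    """Probability D in [0, 1] of dispersing (subordinates) or of staying a
    floater rather than joining a group (floaters).

    SCALAR variant: D = clamp(beta, 0, 1), where 0 is certain philopatry and
    1 absolute dispersal.  RANK_NORM variant: a logistic reaction norm of
    dominance, D = 1 / (1 + exp(beta_R * R - beta_0)).
    """
    scalar = (isinstance(genome, Genome) or np.ndim(genome) == 1) and np.ndim(R) == 0
    g = _genes(genome)
    if variant is DispersalNorm.SCALAR:
        d = np.clip(g[:, BETA], 0.0, 1.0)
    else:
        R = np.asarray(R, dtype=np.float64)
        with np.errstate(over="ignore"):
            d = 1.0 / (1.0 + np.exp(g[:, BETA_R] * R - g[:, BETA_0]))
    return float(d[0]) if scalar else d


def task_probability(genome, R):
    """Probability T of choosing the defensive task this cycle.

    T = 1 / (1 + exp(gamma_R * R - gamma_0)).  T near 1 means lifelong
    defense specialists, T near 0 lifelong workers; gamma_R != 0 produces
    dominance-dependent task switching (age/rank polyethism).
    """
    scalar = (isinstance(genome, Genome) or np.ndim(genome) == 1) and np.ndim(R) == 0
    g = _genes(genome)
    R = np.asarray(R, dtype=np.float64)
    with np.errstate(over="ignore"):
        t = 1.0 / (1.0 + np.exp(g[:, GAMMA_R] * R - g[:, GAMMA_0]))
    return float(t[0]) if scalar else t


def dominance_value(t, y_h: float, H_work):
    """Dominance (competitiveness for a breeding vacancy).

    R = max(0, t - y_h * H_work): dominance grows with age t, a proxy for
    resource-holding potential, and is reduced by this cycle's work effort.
    The work cost is not cumulative over time.
    """
    r = np.maximum(0.0, np.asarray(t, dtype=np.float64) - y_h * np.asarray(H_work, dtype=np.float64))
    return float(r) if r.ndim == 0 else r


def mutate(genes: np.ndarray, mu: float, sigma_mu: float,
           rng: np.random.Generator) -> np.ndarray:
    """Transmit parental genomes with per-locus mutation.

    Independently for each locus (the neutral one included), with
    probability ``mu`` a Normal(0, sigma_mu) perturbation is added to the
    inherited allelic value.  Draw order is part of the engine contract:
    one uniform per (offspring, locus) in row-major order, then one
    normal per *mutating* (offspring, locus) in row-major order.
    """
    genes = np.atleast_2d(np.asarray(genes, dtype=np.float64))
    u = rng.random(genes.shape)
    hit = u < mu
    out = genes.copy()
    out[hit] += rng.normal(0.0, sigma_mu, size=int(hit.sum()))
    return out


def estimate_relatedness(breeder_neutral, helper_neutral) -> float:
    """Within-group relatedness as a neutral-marker regression slope.

    Ordinary-least-squares slope of each helper's neutral allelic value on
    its breeder's, one datum per current helper.  Returns NaN (missing)
    with fewer than 2 pairs or zero breeder-side variance, rather than
    raising.
    """
    x = np.asarray(breeder_neutral, dtype=np.float64)
    y = np.asarray(helper_neutral, dtype=np.float64)
    if x.size < 2:
        return float("nan")
    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0.0:
        return float("nan")
    return float(np.sum((x - xm) * (y - y.mean())) / sxx)
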