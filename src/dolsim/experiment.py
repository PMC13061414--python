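"""Replicate and scenario-grid runner.

Reproduces the model's experimental design — benefit modes x fecundity
modes x environmental harshness x defense cost, replicated with derived
seeds — and packages per-run trait trajectories with equilibrium-window
summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .model_core import (
    ExtinctionError, Parameters, ScenarioConfig, init_population,
    validate_parameters,
)
from .lifecycle import step_cycle
from .stats_io import SummaryRecord, records_to_frame, summarize

__all__ = [
    "RunResult",
    "run_replicate",
    "detect_equilibrium",
    "derive_seed",
    "run_grid",
    "EVOLVING_ALLELES",
]

log = logging.getLogger("dolsim")

#: allele-mean columns the equilibrium detector watches
EVOLVING_ALLELES = ("mean_alpha", "mean_beta", "mean_beta_0", "mean_beta_R",
                    "mean_gamma_0", "mean_gamma_R")

#: fraction of recorded cycles that defines the equilibrium summary window
EQUILIBRIUM_WINDOW_FRACTION = 0.1


@dataclass
class RunResult:
    """One replicate: configuration echo, thinned time series, equilibrium means."""

    params: Parameters
    scenario: ScenarioConfig
    seed: int
    records: pd.DataFrame          #: one row per recorded cycle
    equilibrium: dict              #: metric -> mean over the final-window records
    n_cycles_run: int


def _equilibrium_summary(frame: pd.DataFrame) -> dict:
    n_tail = max(1, int(round(EQUILIBRIUM_WINDOW_FRACTION * len(frame))))
    tail = frame.iloc[-n_tail:]
    out = {col: float(tail[col].mean()) for col in frame.columns if col != "cycle"}
    # relatedness pooled over the window: single-cycle slopes are unstable
    # when few breeder-helper pairs exist, so combine the centered
    # components of every recorded cycle into one regression
    sxx = float(tail["rel_sxx"].sum())
    out["relatedness_pooled"] = float(tail["rel_sxy"].sum() / sxx) if sxx > 0 else float("nan")
    return out


def run_replicate(params: Parameters, scenario: ScenarioConfig,
                  seed: int | None = None, thin: int = 100,
                  equilibrium_window: int | None = None,
                  equilibrium_tol: float = 1e-4,
                  progress_every: int = 10_000) -> RunResult:
    """Run one replicate for ``params.n_cycles`` cycles (or to equilibrium).

    Deterministic given (params, scenario, seed).  A summary record is
    taken every ``thin`` cycles (and at the final cycle).  If
    ``equilibrium_window`` is given, the run stops early once every
    evolving allele-mean trajectory is flat per :func:`detect_equilibrium`;
    by default the run length is fixed.

    Raises
    ------
    ExtinctionError
        When no individual remains, with the cycle of extinction.
    """
    params, scenario = validate_parameters(params, scenario)
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    records: list[SummaryRecord] = []
    n_run = 0
    for cycle in range(1, params.n_cycles + 1):
        tally = step_cycle(pop, params, scenario, rng)
        n_run = cycle
        if pop.n == 0:
            raise ExtinctionError(cycle)
        if cycle % thin == 0 or cycle == params.n_cycles:
            records.append(summarize(pop, tally, params, scenario))
        if progress_every and cycle % progress_every == 0:
            log.info("cycle %d/%d: N=%d, floaters=%d",
                     cycle, params.n_cycles, pop.n, pop.n_floaters)
        if (equilibrium_window is not None and cycle % thin == 0
                and len(records) >= 2 * equilibrium_window):
            series = np.array([[getattr(r, a) for a in EVOLVING_ALLELES]
                               for r in records])
            if detect_equilibrium(series, equilibrium_window, equilibrium_tol):
                break
    frame = records_to_frame(records)
    return RunResult(params=params, scenario=scenario, seed=seed,
                     records=frame, equilibrium=_equilibrium_summary(frame),
                     n_cycles_run=n_run)


def detect_equilibrium(series, window: int, tol: float) -> bool:
    """Flatness test for allele-mean trajectories.

    True when, for every column, the OLS slope over the last ``window``
    records is below ``tol`` in magnitude and the last-window mean moved
    by less than ``tol`` relative to the window before it.  Series shorter
    than two windows are never at equilibrium.
    """
    series = np.atleast_2d(np.asarray(series, dtype=np.float64))
    if series.shape[0] == 1:
        series = series.T
    n = series.shape[0]
    if n < 2 * window:
        return False
    last = series[-window:]
    prev = series[-2 * window:-window]
    x = np.arange(window) - (window - 1) / 2.0
    denom = np.sum(x * x)
    slopes = x @ (last - last.mean(axis=0)) / denom
    dmeans = last.mean(axis=0) - prev.mean(axis=0)
    return bool(np.all(np.abs(slopes) < tol) and np.all(np.abs(dmeans) < tol))


def derive_seed(master_seed: int, cell_index: int, replicate_index: int) -> int:
    """Stable replicate seed from (master seed, grid cell, replicate)."""
    ss = np.random.SeedSequence([master_seed, cell_index, replicate_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_grid(base_params: Parameters, base_scenario: ScenarioConfig,
             grid_spec: dict, n_replicates: int, master_seed: int,
             **run_kwargs) -> dict:
    """Cartesian product of grid values x replicates.

    ``grid_spec`` maps field names (of either :class:`Parameters` or
    :class:`ScenarioConfig`, e.g. ``m``, ``x_h``, ``benefit_mode``) to
    value lists.  Returns a dict keyed by cell — a tuple of (name, value)
    pairs — whose values are lists of :class:`RunResult` or, for failed
    replicates, the exception; failures never abort the grid.
    """
    pnames = {f.name for f in dc_fields(Parameters)}
    snames = {f.name for f in dc_fields(ScenarioConfig)}
    names = list(grid_spec)
    out: dict = {}
    for cell_index, values in enumerate(itertools.product(*(grid_spec[n] for n in names))):
        cell = tuple(zip(names, values))
        params, scenario = base_params, base_scenario
        for name, value in cell:
            if name in pnames:
                params = params.replace(**{name: value})
            elif name in snames:
                scenario = scenario.replace(**{name: value})
            else:
                raise KeyError(f"unknown grid field {name!r}")
        results: list = []
        for rep in range(n_replicates):
            seed = derive_seed(master_seed, cell_index, rep)
            try:
                results.append(run_replicate(params, scenario, seed=seed, **run_kwargs))
            except ExtinctionError as exc:
                log.warning("cell %s replicate %d: %s", cell, rep, exc)
                results.append(exc)
        out[cell] = results
    return out
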