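"""Population summaries and tabular output.

Summary metrics mirror the standard equilibrium table of the model: mean
dispersal propensity, realized survival, group size (± SD), floater count,
helper/floater dominance ratio, and within-group relatedness, plus allele
means/SDs and mean help and task probability.

All files are TSV ('.' decimal, ``NA`` for missing) with the full
configuration echoed as ``#``-prefixed header comments for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior_genetics import (
    dispersal_propensity,
    dominance_value,
    estimate_relatedness,
    express_help,
    task_probability,
)
from .lifecycle import CycleTally
from .model_core import (
    GAMMA_0, GAMMA_R, LOCUS_NAMES, N_LOCI, NEUTRAL,
    Parameters, Population, Role, ScenarioConfig, Task, config_lines,
)

__all__ = [
    "SummaryRecord",
    "summarize",
    "reaction_norm_table",
    "write_timeseries",
    "read_timeseries",
    "write_summary",
    "aggregate_grid",
]


@dataclass
class SummaryRecord:
    """Snapshot of the population at the end of one breeding cycle.

    Means are taken over currently alive individuals; metrics whose
    reference class is empty (e.g. the rank ratio with no floaters, or
    relatedness with < 2 breeder-helper pairs) are NaN, never an error.
    """

    cycle: int
    mean_alpha: float
    sd_alpha: float
    mean_beta: float
    sd_beta: float
    mean_beta_0: float
    sd_beta_0: float
    mean_beta_R: float
    sd_beta_R: float
    mean_gamma_0: float
    sd_gamma_0: float
    mean_gamma_R: float
    sd_gamma_R: float
    mean_neutral: float
    sd_neutral: float
    mean_dispersal: float      #: phenotypic D over subordinates + floaters
    mean_help: float           #: phenotypic H over subordinates
    mean_task_prob: float      #: defensive-task probability T over subordinates
    group_size_mean: float     #: over occupied territories (breeder + subordinates)
    group_size_sd: float       #: population SD over occupied territories
    n_floaters: int
    n_total: int
    survival_overall: float    #: realized survivors / at-risk, all roles pooled
    survival_breeders: float
    survival_subordinates: float
    survival_floaters: float
    rank_ratio: float          #: mean helper dominance / mean floater dominance
    relatedness: float         #: breeder-helper neutral-locus regression slope
    rel_n_pairs: int           #: breeder-helper pairs behind the regression
    rel_sxx: float             #: centered breeder-side sum of squares
    rel_sxy: float             #: centered breeder-helper cross-product


def _mean(x) -> float:
    return float(np.mean(x)) if len(x) else float("nan")


def summarize(pop: Population, tally: CycleTally, params: Parameters,
              scenario: ScenarioConfig) -> SummaryRecord:
    """Compute a :class:`SummaryRecord` for the current population state."""
    subs = pop.role == Role.SUBORDINATE
    floats_ = pop.role == Role.FLOATER
    nonbreed = subs | floats_

    allele_stats = {}
    for k, name in enumerate(LOCUS_NAMES):
        col = pop.genes[:, k]
        allele_stats[f"mean_{name}"] = _mean(col)
        allele_stats[f"sd_{name}"] = float(np.std(col)) if pop.n else float("nan")

    if nonbreed.any():
        D = dispersal_propensity(pop.genes[nonbreed],
                                 pop.age[nonbreed].astype(float),
                                 scenario.dispersal_norm)
        mean_D = float(np.mean(D))
    else:
        mean_D = float("nan")

    if subs.any():
        mean_H = float(np.mean(express_help(pop.genes[subs])))
        mean_T = float(np.mean(task_probability(pop.genes[subs],
                                                pop.age[subs].astype(float))))
    else:
        mean_H = mean_T = float("nan")

    b_idx = pop.breeder_of()
    occupied = b_idx >= 0
    if occupied.any():
        sizes = pop.group_sizes()[occupied]
        gs_mean, gs_sd = float(np.mean(sizes)), float(np.std(sizes))
    else:
        gs_mean = gs_sd = float("nan")

    # dominance with this cycle's work cost still applied
    H = express_help(pop.genes)
    H_work = np.where(pop.task == np.int8(Task.WORK), H, 0.0)
    R = dominance_value(pop.age, params.y_h, H_work)
    rank_ratio = (_mean(R[subs]) / _mean(R[floats_])
                  if subs.any() and floats_.any() else float("nan"))

    helper_groups = pop.group[subs]
    with_breeder = occupied[helper_groups]
    breeder_vals = pop.genes[b_idx[helper_groups[with_breeder]], NEUTRAL]
    helper_vals = pop.genes[np.nonzero(subs)[0][with_breeder], NEUTRAL]
    relatedness = estimate_relatedness(breeder_vals, helper_vals)
    # centered components so sparse cycles can be pooled into one stable
    # regression over a window (few pairs make single-cycle slopes noisy)
    if breeder_vals.size >= 2:
        rel_sxx = float(np.sum((breeder_vals - breeder_vals.mean()) ** 2))
        rel_sxy = float(np.sum((breeder_vals - breeder_vals.mean())
                               * (helper_vals - helper_vals.mean())))
    else:
        rel_sxx = rel_sxy = 0.0

    return SummaryRecord(
        cycle=pop.cycle,
        **allele_stats,
        mean_dispersal=mean_D,
        mean_help=mean_H,
        mean_task_prob=mean_T,
        group_size_mean=gs_mean,
        group_size_sd=gs_sd,
        n_floaters=pop.n_floaters,
        n_total=pop.n,
        survival_overall=tally.survival_overall,
        survival_breeders=tally.survival_of(Role.BREEDER),
        survival_subordinates=tally.survival_of(Role.SUBORDINATE),
        survival_floaters=tally.survival_of(Role.FLOATER),
        rank_ratio=rank_ratio,
        relatedness=relatedness,
        rel_n_pairs=int(breeder_vals.size),
        rel_sxx=rel_sxx,
        rel_sxy=rel_sxy,
    )


def reaction_norm_table(gamma_0: float, gamma_R: float,
                        R_grid) -> pd.DataFrame:
    """Tabulate the evolved task reaction norm T(R) on a dominance grid.

    Evaluates the defensive-task probability at replica-averaged
    (gamma_0, gamma_R) for plotting or export.
    """
    R_grid = np.asarray(R_grid, dtype=np.float64)
    genes = np.zeros((R_grid.size, N_LOCI))
    genes[:, GAMMA_0] = gamma_0
    genes[:, GAMMA_R] = gamma_R
    T = task_probability(genes, R_grid)
    return pd.DataFrame({"R": R_grid, "T": T})


# ---------------------------------------------------------------------------
# TSV writers / readers


def _header(params: Parameters, scenario: ScenarioConfig) -> list[str]:
    return [f"# {line}" for line in config_lines(params, scenario)]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_timeseries(records, path, params: Parameters,
                     scenario: ScenarioConfig) -> None:
    """One row per recorded cycle; config echoed as '#' header comments."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    _write_tsv(frame, path, params, scenario)


def _write_tsv(frame: pd.DataFrame, path, params, scenario) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(_header(params, scenario)) + "\n")
            frame.to_csv(fh, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def read_timeseries(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_timeseries`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")


def write_summary(results, path, params: Parameters,
                  scenario: ScenarioConfig) -> None:
    """One row per replicate: its seed plus equilibrium-window means."""
    rows = []
    for res in results:
        row = {"seed": res.seed, "n_cycles_run": res.n_cycles_run}
        row.update(res.equilibrium)
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), path, params, scenario)


def aggregate_grid(cell_results: dict) -> pd.DataFrame:
    """Across-replicate mean and SD of every metric for each grid cell.

    ``cell_results`` maps a cell key (tuple of (name, value) pairs) to the
    list of its replicate results.  One output row per cell, mirroring the
    layout of the model's equilibrium table (scenario columns first, then
    metric mean/SD pairs).
    """
    rows = []
    for cell, results in cell_results.items():
        row = dict(cell)
        ok = [r for r in results if not isinstance(r, Exception)]
        row["n_replicates"] = len(ok)
        row["n_failed"] = len(results) - len(ok)
        if ok:
            frame = pd.DataFrame([r.equilibrium for r in ok])
            for col in frame.columns:
                row[f"{col}_mean"] = frame[col].mean()
                row[f"{col}_sd"] = frame[col].std(ddof=1) if len(ok) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
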