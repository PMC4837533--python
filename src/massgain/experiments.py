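"""Replication engine: replicated simulations, grids, CIs and comparisons.

The study design evaluates every strategy over a TSP grid (0.05 to 0.95 in
steps of 0.05) with 1000 replicate populations of N = 400 per cell, reporting
mean gain and the 95% confidence interval 1.96 * s / sqrt(n).  Two entry
points are provided:

- :func:`run_cell` simulates one (scenario, population, strategy, TSP[, SP_M])
  cell with fresh, fully keyed replicate streams, so any single cell is
  independently reproducible.
- :func:`sweep` evaluates many cells on *shared* replicate populations
  (common random numbers): replicate r's stream depends only on
  (root_seed, r), populations are simulated once per replicate and every
  requested cell is scored on them.  Paired cells are therefore positively
  correlated, which sharpens comparisons between strategies and grid points
  without biasing any mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analytic
from .genetic_model import (
    TraitTestScenario,
    marker_table_for,
    scenario_grid,
    table1_frame,
)
from .simulator import DEFAULT_N, simulate_population
from .strategies import (
    STRATEGIES,
    index_weights,
    n_selected,
    rank_seedlings,
    select_index,
    select_marker_only,
    select_phenotype_only,
    select_two_stage,
)

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 1000
DEFAULT_GRID_STEP = 0.05

_POP_CODES = {"three_genotype": 1, "nine_genotype": 2}
_DOM_CODES = {None: 0, "none": 1, "partial": 2, "complete": 3}
_STRATEGY_CODES = {s: i + 1 for i, s in enumerate(STRATEGIES)}


@dataclass(frozen=True)
class GainEstimate:
    """Mean realized gain over replicates with its 95% confidence interval."""

    strategy: str
    tsp: float
    sp_m: float | None
    mean_gain: float
    sd: float
    n_reps: int
    ci_low: float
    ci_high: float
    scenario_id: int | None = None
    population_kind: str | None = None
    dominance: str | None = None


def tsp_grid(step: float = DEFAULT_GRID_STEP) -> list[float]:
    """Total selection proportions {step, 2*step, ..., 1 - step}."""
    denom = _grid_denominator(step)
    return [i / denom for i in range(1, denom)]


def spm_grid(tsp: float, step: float = DEFAULT_GRID_STEP) -> list[float]:
    """First-stage proportions {TSP, TSP + step, ..., 1}; TSP must be on-grid."""
    denom = _grid_denominator(step)
    numerator = round(tsp * denom)
    if not 1 <= numerator <= denom or abs(tsp - numerator / denom) > 1e-9:
        raise ValueError(f"TSP={tsp} is not on the grid with step {step}")
    return [i / denom for i in range(numerator, denom + 1)]


def _grid_denominator(step: float) -> int:
    denom = round(1.0 / step)
    if denom < 2 or abs(denom * step - 1.0) > 1e-9:
        raise ValueError(f"grid step {step} does not divide 1 evenly")
    return denom


def summarize_gains(
    gains: np.ndarray,
    *,
    strategy: str,
    tsp: float,
    sp_m: float | None = None,
    scenario_id: int | None = None,
    population_kind: str | None = None,
    dominance: str | None = None,
) -> GainEstimate:
    """Mean, s.d. and 95% CI (1.96 * s / sqrt(n)) of replicate gains.

    With a single replicate the s.d. is defined as 0, so the estimate is
    still emitted (with a degenerate CI).
    """
    gains = np.asarray(gains, dtype=float)
    n = gains.size
    if n < 1:
        raise ValueError("at least one replicate is required")
    mean = float(gains.mean())
    sd = float(gains.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / math.sqrt(n)
    return GainEstimate(
        strategy=strategy, tsp=tsp, sp_m=sp_m,
        mean_gain=mean, sd=sd, n_reps=n,
        ci_low=mean - half, ci_high=mean + half,
        scenario_id=scenario_id, population_kind=population_kind,
        dominance=dominance,
    )


def _cell_seed(root_seed, scenario_id, population_kind, dominance, strategy,
               tsp, sp_m, rep) -> np.random.SeedSequence:
    def key(x):
        return 0 if x is None else int(round(x * 1_000_000))

    return np.random.SeedSequence(
        root_seed,
        spawn_key=(
            scenario_id,
            _POP_CODES[population_kind],
            _DOM_CODES[dominance],
            _STRATEGY_CODES[strategy],
            key(tsp),
            key(sp_m),
            rep,
        ),
    )


def run_cell(
    scenario: TraitTestScenario,
    population_kind: str,
    dominance: str | None,
    strategy: str,
    tsp: float,
    sp_m: float | None = None,
    n_reps: int = DEFAULT_N_REPS,
    root_seed: int = 0,
    N: int = DEFAULT_N,
) -> GainEstimate:
    """Simulate and select one experimental cell over independent replicates."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be at least 1, got {n_reps}")
    if strategy == "two_stage" and sp_m is None:
        raise ValueError("two_stage requires sp_m")
    table = marker_table_for(scenario, population_kind, dominance)
    gains = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(
            _cell_seed(root_seed, scenario.scenario_id, population_kind,
                       dominance, strategy, tsp, sp_m, rep)
        )
        pop = simulate_population(table, scenario, N=N, rng=rng)
        if strategy == "phenotype_only":
            result = select_phenotype_only(pop, tsp, rng)
        elif strategy == "marker_only":
            result = select_marker_only(pop, tsp, rng)
        elif strategy == "two_stage":
            result = select_two_stage(pop, tsp, sp_m, rng)
        else:
            result = select_index(pop, tsp, rng=rng)
        gains[rep] = result.delta_g
    return summarize_gains(
        gains, strategy=strategy, tsp=tsp,
        sp_m=sp_m if strategy == "two_stage" else None,
        scenario_id=scenario.scenario_id,
        population_kind=population_kind, dominance=dominance,
    )


def sweep(
    scenario: TraitTestScenario,
    table,
    *,
    strategies=STRATEGIES,
    tsp_values=None,
    spm_values=None,
    grid_step: float = DEFAULT_GRID_STEP,
    n_reps: int = DEFAULT_N_REPS,
    root_seed: int = 0,
    N: int = DEFAULT_N,
    return_replicates: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Evaluate many (strategy, TSP[, SP_M]) cells on shared replicates.

    Returns one row per cell with mean gain, s.d. and 95% CI.  Within a
    replicate all cells see the same population and the same ranking
    tie-breaks, so two_stage at SP_M = 1 (or SP_M = TSP) reproduces
    phenotype-only (marker-only) selections exactly.

    ``spm_values`` restricts the two-stage SP_M grid (default: the full grid
    from TSP to 1); infeasible combinations (SP_M < TSP) are skipped.  With
    ``return_replicates`` the per-replicate gain matrix (n_reps x n_cells,
    columns in row order of the summary frame) is returned as well, for
    paired replicate-level comparisons between cells.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be at least 1, got {n_reps}")
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    tsps = list(tsp_values) if tsp_values is not None else tsp_grid(grid_step)

    # Fixed cell list: (strategy, tsp, sp_m, k_final, k_stage1)
    cells: list[tuple[str, float, float | None, int, int | None]] = []
    for strat in strategies:
        for t in tsps:
            k = n_selected(t, N)
            if strat == "two_stage":
                grid = spm_values if spm_values is not None else spm_grid(t, grid_step)
                for s in grid:
                    if s + 1e-9 < t:
                        continue
                    k1 = n_selected(s, N)
                    if k1 < k:
                        continue
                    cells.append((strat, t, s, k, k1))
            else:
                cells.append((strat, t, None, k, None))

    want_pheno = any(c[0] in ("phenotype_only", "two_stage") for c in cells)
    want_marker = any(c[0] in ("marker_only", "two_stage") for c in cells)
    want_index = any(c[0] == "index" for c in cells)
    b_z, b_m = index_weights(scenario.H, scenario.P) if want_index else (1.0, 0.0)

    sums = np.zeros(len(cells))
    sumsq = np.zeros(len(cells))
    gains = np.empty(len(cells))
    replicate_gains = np.empty((n_reps, len(cells))) if return_replicates else None

    for rep in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(root_seed, spawn_key=(rep,))
        )
        pop = simulate_population(table, scenario, N=N, rng=rng)
        g = pop.g
        mean_all = float(g.mean())

        pheno_order = rank_seedlings(pop.z, rng) if want_pheno else None
        marker_order = rank_seedlings(pop.g_M, rng) if want_marker else None
        if want_index:
            if math.isinf(b_m):
                index_order = rank_seedlings(pop.g_M, rng, secondary=pop.z)
            else:
                index_order = rank_seedlings(b_z * pop.z + b_m * pop.g_M, rng)

        cum = {}
        if want_pheno:
            cum["phenotype_only"] = np.cumsum(g[pheno_order])
        if want_marker:
            cum["marker_only"] = np.cumsum(g[marker_order])
        if want_index:
            cum["index"] = np.cumsum(g[index_order])

        # Two-stage survivor prefix sums, cached per stage-1 count.
        surv_cum: dict[int, np.ndarray] = {}
        in_stage1 = np.zeros(N, dtype=bool)
        for _, _, _, _, k1 in cells:
            if k1 is None or k1 in surv_cum:
                continue
            in_stage1[:] = False
            in_stage1[marker_order[:k1]] = True
            survivors = pheno_order[in_stage1[pheno_order]]
            surv_cum[k1] = np.cumsum(g[survivors])

        for j, (strat, _, _, k, k1) in enumerate(cells):
            if strat == "two_stage":
                gains[j] = surv_cum[k1][k - 1] / k - mean_all
            else:
                gains[j] = cum[strat][k - 1] / k - mean_all
        sums += gains
        sumsq += gains * gains
        if replicate_gains is not None:
            replicate_gains[rep] = gains

    mean = sums / n_reps
    if n_reps > 1:
        var = np.maximum(sumsq - n_reps * mean * mean, 0.0) / (n_reps - 1)
    else:
        var = np.zeros_like(mean)
    sd = np.sqrt(var)
    half = 1.96 * sd / math.sqrt(n_reps)

    frame = pd.DataFrame(
        {
            "scenario_id": scenario.scenario_id,
            "population_kind": table.population_kind,
            "dominance": table.dominance,
            "strategy": [c[0] for c in cells],
            "tsp": [c[1] for c in cells],
            "sp_m": [c[2] for c in cells],
            "mean_gain": mean,
            "sd": sd,
            "n_reps": n_reps,
            "ci_low": mean - half,
            "ci_high": mean + half,
        }
    )
    if return_replicates:
        return frame, replicate_gains
    return frame


def two_stage_optima(gains: pd.DataFrame) -> pd.DataFrame:
    """Per-TSP optimal simulated two-stage rows; ties take the largest SP_M."""
    ts = gains[gains["strategy"] == "two_stage"]
    if ts.empty:
        return ts
    keys = [c for c in ("scenario_id", "population_kind", "dominance", "tsp")
            if c in ts.columns]
    ordered = ts.sort_values(keys[:-1] + ["tsp", "mean_gain", "sp_m"])
    return ordered.groupby(keys, dropna=False).tail(1).reset_index(drop=True)


def correlate_derived_simulated(derived, simulated) -> float:
    """Pearson correlation between derived and simulated gain curves.

    Returns NaN (with a log warning) when either vector has zero variance,
    where the coefficient is undefined.
    """
    d = np.asarray(derived, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if d.shape != s.shape:
        raise ValueError("derived and simulated vectors must have equal length")
    if d.size < 3:
        raise ValueError("at least 3 paired values are required")
    if d.std() == 0.0 or s.std() == 0.0:
        logger.warning("correlation undefined: a gain vector has zero variance")
        return math.nan
    return float(np.corrcoef(d, s)[0, 1])


def derived_gain_table(
    scenario: TraitTestScenario,
    table,
    tsp_values=None,
    step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Closed-form gains per strategy over the TSP grid (two-stage per SP_M)."""
    tsps = list(tsp_values) if tsp_values is not None else tsp_grid(step)
    rows = []

    def add(strategy, t, s, value):
        rows.append(
            {
                "scenario_id": scenario.scenario_id,
                "population_kind": table.population_kind,
                "dominance": table.dominance,
                "strategy": strategy,
                "tsp": t,
                "sp_m": s,
                "delta_g_derived": value,
            }
        )

    for t in tsps:
        add("phenotype_only", t, None,
            analytic.gain_phenotype_only(scenario.H, scenario.V_P, t))
        add("marker_only", t, None, analytic.gain_marker_only_exact(table, t))
        add("index", t, None,
            analytic.gain_index(scenario.H, scenario.P, scenario.V_P, t))
        for s in spm_grid(t, step):
            add("two_stage", t, s,
                analytic.gain_two_stage(table, scenario.V_B, scenario.V_E, t, s))
    return pd.DataFrame(rows)


def full_experiment(config) -> dict[str, pd.DataFrame]:
    """Run the complete study grid and assemble the output tables.

    Returns a dict of long-format DataFrames: ``table1`` (scenario grid with
    derived effects), ``gains_simulated``, ``gains_derived``,
    ``two_stage_optima`` (derived and simulated optima per TSP) and
    ``correlations`` (derived-vs-simulated Pearson r per strategy; two-stage
    correlates the per-TSP optimum curves).  Deterministic for a fixed
    config.
    """
    scenarios = scenario_grid(config.V_P, config.H_levels, config.P_levels)
    tsps = tsp_grid(config.grid_step)

    cases: list[tuple[str, str | None]] = []
    if "three_genotype" in config.populations:
        cases += [("three_genotype", dom) for dom in config.dominance_cases]
    if "nine_genotype" in config.populations:
        cases.append(("nine_genotype", None))

    sim_frames, derived_frames, optima_rows, corr_rows = [], [], [], []
    for scenario in scenarios:
        for population_kind, dominance in cases:
            logger.info(
                "scenario %d (H=%.1f, P=%.1f) %s/%s: %d reps, seed %d",
                scenario.scenario_id, scenario.H, scenario.P,
                population_kind, dominance, config.n_reps, config.root_seed,
            )
            table = marker_table_for(scenario, population_kind, dominance)
            sim = sweep(
                scenario, table, tsp_values=tsps, grid_step=config.grid_step,
                n_reps=config.n_reps, root_seed=config.root_seed, N=config.N,
            )
            derived = derived_gain_table(scenario, table, tsps, config.grid_step)
            sim_frames.append(sim)
            derived_frames.append(derived)

            sim_opt = two_stage_optima(sim)
            derived_ts = derived[derived["strategy"] == "two_stage"]
            for t in tsps:
                spm_d, gain_d = analytic.optimal_two_stage(
                    table, scenario.V_B, scenario.V_E, t, spm_grid(t, config.grid_step)
                )
                row_s = sim_opt[np.isclose(sim_opt["tsp"], t)].iloc[0]
                optima_rows.append(
                    {
                        "scenario_id": scenario.scenario_id,
                        "population_kind": population_kind,
                        "dominance": dominance,
                        "tsp": t,
                        "sp_m_derived": spm_d,
                        "delta_g_derived": gain_d,
                        "sp_m_simulated": row_s["sp_m"],
                        "delta_g_simulated": row_s["mean_gain"],
                        "ci_low": row_s["ci_low"],
                        "ci_high": row_s["ci_high"],
                    }
                )

            for strategy in STRATEGIES:
                if strategy == "two_stage":
                    d_curve = [r["delta_g_derived"] for r in optima_rows[-len(tsps):]]
                    s_curve = [r["delta_g_simulated"] for r in optima_rows[-len(tsps):]]
                else:
                    d_sub = derived[derived["strategy"] == strategy]
                    s_sub = sim[sim["strategy"] == strategy]
                    d_curve = d_sub.sort_values("tsp")["delta_g_derived"].to_numpy()
                    s_curve = s_sub.sort_values("tsp")["mean_gain"].to_numpy()
                corr_rows.append(
                    {
                        "scenario_id": scenario.scenario_id,
                        "population_kind": population_kind,
                        "dominance": dominance,
                        "strategy": strategy,
                        "pearson_r": correlate_derived_simulated(d_curve, s_curve),
                    }
                )

    return {
        "table1": table1_frame(scenarios),
        "gains_simulated": pd.concat(sim_frames, ignore_index=True),
        "gains_derived": pd.concat(derived_frames, ignore_index=True),
        "two_stage_optima": pd.DataFrame(optima_rows),
        "correlations": pd.DataFrame(corr_rows),
    }
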