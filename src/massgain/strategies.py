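"""The four seedling-selection strategies and realized genetic gain.

All strategies retain ``round(TSP * N)`` seedlings:

- *phenotype-only*: top seedlings by phenotypic value z.
- *marker-only*: genotype classes in descending order of class mean; the
  boundary class is thinned uniformly at random to reach the target count.
- *two-stage*: marker-only truncation to ``round(SP_M * N)`` survivors, then
  phenotypic truncation among survivors (SP_P = TSP / SP_M).
- *index*: top seedlings by ``I = b_z * z + b_m * m`` with m the seedling's
  class-mean marker effect and weight ratio b_m/b_z = (1/H - 1)/(1 - P).

Realized genetic gain is the increase in mean genotypic value of the selected
seedlings over the whole pre-selection population.  Ties (certain under
zero-noise scenarios, probability zero otherwise) are broken uniformly at
random so degenerate scenarios behave like marker-only random culling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulator import SeedlingPopulation

STRATEGIES = ("phenotype_only", "marker_only", "two_stage", "index")


@dataclass(frozen=True)
class SelectionResult:
    strategy: str
    tsp: float
    sp_m: float | None
    selected_ids: np.ndarray
    delta_g: float


def n_selected(tsp: float, N: int) -> int:
    """Retained count round(TSP * N), ties to even; must be at least 1."""
    if not 0 < tsp <= 1:
        raise ValueError(f"selection proportion must be in (0, 1], got {tsp}")
    k = round(tsp * N)
    if k < 1:
        raise ValueError(f"TSP={tsp} with N={N} would retain no seedlings")
    return k


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def rank_seedlings(
    primary: np.ndarray,
    rng: np.random.Generator,
    secondary: np.ndarray | None = None,
) -> np.ndarray:
    """Seedling ids in descending order of score, ties uniformly random.

    With ``secondary``, ranking is lexicographic (primary, then secondary)
    before the random tie-break.
    """
    n = primary.shape[0]
    perm = rng.permutation(n)
    if secondary is None:
        order = np.argsort(-primary[perm], kind="stable")
    else:
        # np.lexsort is stable; leftover ties keep the random perm order.
        order = np.lexsort((-secondary[perm], -primary[perm]))
    return perm[order]


def realized_gain(pop: SeedlingPopulation, selected_ids: np.ndarray) -> float:
    """Mean g of the selected seedlings minus mean g of the whole population."""
    selected_ids = np.asarray(selected_ids)
    if selected_ids.size == 0:
        raise ValueError("selection is empty")
    return float(pop.g[selected_ids].mean() - pop.g.mean())


def _result(pop, strategy, tsp, sp_m, ids) -> SelectionResult:
    return SelectionResult(
        strategy=strategy, tsp=tsp, sp_m=sp_m,
        selected_ids=ids, delta_g=realized_gain(pop, ids),
    )


def select_phenotype_only(
    pop: SeedlingPopulation, tsp: float, rng=None
) -> SelectionResult:
    """Retain the round(TSP*N) seedlings with highest phenotypic values."""
    k = n_selected(tsp, pop.N)
    ids = rank_seedlings(pop.z, _as_rng(rng))[:k]
    return _result(pop, "phenotype_only", tsp, None, ids)


def select_marker_only(
    pop: SeedlingPopulation, tsp: float, rng=None
) -> SelectionResult:
    """Retain seedlings with highest marker effects, random within-class culling."""
    k = n_selected(tsp, pop.N)
    ids = rank_seedlings(pop.g_M, _as_rng(rng))[:k]
    return _result(pop, "marker_only", tsp, None, ids)


def select_two_stage(
    pop: SeedlingPopulation, tsp: float, sp_m: float, rng=None
) -> SelectionResult:
    """Marker truncation to SP_M, then phenotypic truncation to TSP.

    The final retained count is round(TSP*N) exactly; the stage-2 proportion
    is implied (SP_P = TSP/SP_M).
    """
    if sp_m < tsp:
        raise ValueError(f"SP_M ({sp_m}) must be at least TSP ({tsp})")
    rng = _as_rng(rng)
    k = n_selected(tsp, pop.N)
    k1 = n_selected(sp_m, pop.N)
    if k1 < k:
        raise ValueError(
            f"stage-1 count {k1} is below the final count {k} "
            f"(SP_M={sp_m}, TSP={tsp}, N={pop.N})"
        )
    stage1 = rank_seedlings(pop.g_M, rng)[:k1]
    order2 = rank_seedlings(pop.z[stage1], rng)
    ids = stage1[order2[:k]]
    return _result(pop, "two_stage", tsp, sp_m, ids)


def index_weights(H: float, P: float) -> tuple[float, float]:
    """Index weights (b_z, b_m) with b_z = 1 and b_m = (1/H - 1)/(1 - P).

    H = 1 gives b_m = 0 (phenotype carries all information); P = 1 with H < 1
    gives b_m = inf, implemented downstream as marker-first lexicographic
    ranking.
    """
    if not 0 < H <= 1:
        raise ValueError(f"H must be in (0, 1], got {H}")
    if not 0 <= P <= 1:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if H == 1:
        return 1.0, 0.0
    if P == 1:
        return 1.0, math.inf
    return 1.0, (1.0 / H - 1.0) / (1.0 - P)


def select_index(
    pop: SeedlingPopulation,
    tsp: float,
    H: float | None = None,
    P: float | None = None,
    rng=None,
) -> SelectionResult:
    """Retain the top round(TSP*N) seedlings by the weighted index I."""
    if H is None:
        H = pop.scenario.H
    if P is None:
        P = pop.scenario.P
    rng = _as_rng(rng)
    k = n_selected(tsp, pop.N)
    b_z, b_m = index_weights(H, P)
    if math.isinf(b_m):
        ids = rank_seedlings(pop.g_M, rng, secondary=pop.z)[:k]
    else:
        ids = rank_seedlings(b_z * pop.z + b_m * pop.g_M, rng)[:k]
    return _result(pop, "index", tsp, None, ids)
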