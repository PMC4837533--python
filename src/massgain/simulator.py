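"""Stochastic simulation of seedling populations.

Each seedling carries a marker genotype (assigned with *exact* class counts,
e.g. 100 MM / 200 Mm / 100 mm at N = 400 in the three-genotype population), a
background genotypic effect ``g_B ~ Normal(0, V_B)`` and an environmental
effect ``e ~ Normal(0, V_E)``.  Genotypic and phenotypic values are

    g = zero_point + g_M + g_B,        z = g + e,

where ``g_M`` is the seedling's class-mean marker effect on the adjusted
scale.  The scale constant (25) is carried inside ``g`` so that ``z = g + e``
holds record by record; it cancels in every genetic-gain computation.

Only g_B and e are stochastic: genotype counts are fixed, not multinomial.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_model import MarkerGenotypeTable, TraitTestScenario

DEFAULT_N = 400

PopulationMoments = namedtuple(
    "PopulationMoments", ["mean_g", "var_g", "mean_z", "var_z"]
)


@dataclass
class SeedlingPopulation:
    """A simulated seedling population (one record per seedling)."""

    scenario: TraitTestScenario
    table: MarkerGenotypeTable
    N: int
    seed: int | None
    genotype: np.ndarray  # class label per seedling
    g_M: np.ndarray  # marker effect, adjusted scale
    g_B: np.ndarray  # background genotypic effect
    e: np.ndarray  # environmental effect
    g: np.ndarray  # genotypic value (includes the zero point)
    z: np.ndarray  # phenotypic value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.N),
                "genotype": self.genotype,
                "g_M": self.g_M,
                "g_B": self.g_B,
                "e": self.e,
                "g": self.g,
                "z": self.z,
            }
        )


def class_counts(table: MarkerGenotypeTable, N: int) -> np.ndarray:
    """Exact per-class seedling counts; N x frequency must be integral."""
    if N < 1:
        raise ValueError(f"N must be at least 1, got {N}")
    counts = table.frequencies_array * N
    rounded = np.rint(counts)
    for label, c in zip(table.labels, counts):
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"N={N} does not yield an integer count for class {label} "
                f"(frequency {c / N:g} gives {c:g} seedlings)"
            )
    return rounded.astype(int)


def _resolve_rng(rng) -> tuple[np.random.Generator, int | None]:
    if rng is None:
        return np.random.default_rng(), None
    if isinstance(rng, np.random.Generator):
        return rng, None
    return np.random.default_rng(rng), int(rng)


def simulate_population(
    table: MarkerGenotypeTable,
    scenario: TraitTestScenario,
    N: int = DEFAULT_N,
    rng: int | np.random.Generator | None = None,
) -> SeedlingPopulation:
    """Simulate one seedling population.

    ``rng`` may be an integer seed, a numpy Generator (for externally managed
    replicate streams) or None for nondeterministic output.  Given the same
    seed, table, scenario and N the population is identical.
    """
    if scenario.V_B < 0 or scenario.V_E < 0:
        raise ValueError("V_B and V_E must be non-negative")
    counts = class_counts(table, N)
    generator, seed = _resolve_rng(rng)

    genotype = np.repeat(np.asarray(table.labels, dtype=object), counts)
    g_M = np.repeat(table.means_array, counts)
    # Scaled standard normals keep the draw count independent of the scenario,
    # which keeps replicate streams aligned across scenarios.
    g_B = math.sqrt(scenario.V_B) * generator.standard_normal(N)
    e = math.sqrt(scenario.V_E) * generator.standard_normal(N)
    g = table.zero_point + g_M + g_B
    z = g + e
    return SeedlingPopulation(
        scenario=scenario, table=table, N=N, seed=seed,
        genotype=genotype, g_M=g_M, g_B=g_B, e=e, g=g, z=z,
    )


def population_moments(pop: SeedlingPopulation) -> PopulationMoments:
    """Arithmetic moments of g and z.

    Variances use the population (divide-by-N) convention so that zero-noise
    populations match the enumerated marker tables exactly.
    """
    if pop.N < 1:
        raise ValueError("population is empty")
    return PopulationMoments(
        mean_g=float(pop.g.mean()),
        var_g=float(pop.g.var()),
        mean_z=float(pop.z.mean()),
        var_z=float(pop.z.var()),
    )
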