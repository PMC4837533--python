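"""Trait-test scenarios and discrete marker-genotype distributions.

The model partitions the phenotypic variance of a seedling trait into a
marker-explained part and everything else,

    V_P = V_G + V_E,        V_G = V_M + V_B,

with broad-sense heritability ``H = V_G / V_P`` and DNA-test predictiveness
``P = V_M / V_G``.  Broad-sense (rather than narrow-sense) heritability is the
relevant quantity because clonal propagation carries dominance and epistatic
effects, not only additive ones, into the deployed cultivar.

Two segregating populations are modeled as discrete distributions of marker
genotype classes.  The three-genotype population segregates at a single
marker-tagged locus (MM : Mm : mm = 1 : 2 : 1) with class means ``a3``, ``d3``
and ``-a3`` on a scale whose zero point is 25; dominance enters through
``d3 in {0, a3/2, a3}``.  The nine-genotype population segregates at two
unlinked loci (a major locus M and a minor locus T) with epistatic overrides
for MMTt (3*a9 instead of 2*a9) and mmTT (-2.5*a9 instead of -a9).  The effect
scalars ``a3`` and ``a9`` are derived so that the frequency-weighted variance
of the class means reproduces the scenario's V_M exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Scale constant added when materializing genotypic/phenotypic values; chosen
#: so most seedlings have positive phenotypes.  It cancels in every gain.
ZERO_POINT = 25.0

#: Heritability / predictiveness levels of the 16-cell scenario grid.
H_LEVELS = (0.2, 0.5, 0.8, 1.0)
P_LEVELS = (0.2, 0.5, 0.8, 1.0)

#: Phenotypic variance shared by all study scenarios (trait units squared).
DEFAULT_V_P = 200.0

#: Dominance-degree cases for the three-genotype population, as d3/a3 ratios.
DOMINANCE_RATIOS = {"none": 0.0, "partial": 0.5, "complete": 1.0}

THREE_GENOTYPE_LABELS = ("MM", "Mm", "mm")
THREE_GENOTYPE_FREQUENCIES = (0.25, 0.5, 0.25)

NINE_GENOTYPE_LABELS = (
    "MMTT", "MMTt", "MMtt", "MmTT", "MmTt", "Mmtt", "mmTT", "mmTt", "mmtt",
)
NINE_GENOTYPE_FREQUENCIES = tuple(f / 16.0 for f in (1, 2, 1, 2, 4, 2, 1, 2, 1))
#: Class means in units of a9.  MMTt and mmTT carry the epistatic overrides.
NINE_GENOTYPE_COEFFICIENTS = (3.0, 3.0, 1.0, 2.0, 1.0, 0.0, -2.5, -2.0, -3.0)


def _weighted_mean_variance(frequencies, values) -> tuple[float, float]:
    f = np.asarray(frequencies, dtype=float)
    v = np.asarray(values, dtype=float)
    mean = float(f @ v)
    var = float(f @ (v * v) - mean * mean)
    return mean, max(var, 0.0)


#: Frequency-weighted variance of the nine-genotype class means at a9 = 1,
#: obtained by enumeration; a9 = sqrt(V_M / this constant).
NINE_GENOTYPE_UNIT_VARIANCE = _weighted_mean_variance(
    NINE_GENOTYPE_FREQUENCIES, NINE_GENOTYPE_COEFFICIENTS
)[1]


@dataclass(frozen=True)
class TraitTestScenario:
    """One (H, P) cell of the trait-test grid with its variance partition.

    All variances are in trait units squared and satisfy
    ``V_P = V_G + V_E`` and ``V_G = V_M + V_B`` exactly.
    """

    scenario_id: int
    H: float
    P: float
    V_P: float
    V_G: float
    V_E: float
    V_M: float
    V_B: float


@dataclass(frozen=True)
class MarkerGenotypeTable:
    """Discrete distribution of marker-genotype classes.

    Class means are stored on the adjusted scale (zero point subtracted);
    :data:`ZERO_POINT` is added only when phenotypes are materialized.
    """

    population_kind: str  # "three_genotype" | "nine_genotype"
    dominance: str | None  # three_genotype only; None for nine_genotype
    zero_point: float
    labels: tuple[str, ...]
    frequencies: tuple[float, ...]
    means: tuple[float, ...]
    effect_scalar: float  # a3 or a9

    @property
    def frequencies_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    @property
    def means_array(self) -> np.ndarray:
        return np.asarray(self.means, dtype=float)

    def mean(self) -> float:
        """Frequency-weighted mean marker effect (adjusted scale)."""
        return _weighted_mean_variance(self.frequencies, self.means)[0]

    def variance(self) -> float:
        """Frequency-weighted variance of the class means (equals V_M)."""
        return _weighted_mean_variance(self.frequencies, self.means)[1]

    def class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "frequency": list(self.frequencies),
                "mean_genotypic_value": list(self.means),
            }
        )


def partition_variance(
    V_P: float, H: float, P: float, scenario_id: int = 0
) -> TraitTestScenario:
    """Partition phenotypic variance given heritability and predictiveness.

    Parameters
    ----------
    V_P : positive phenotypic variance (trait units squared).
    H : broad-sense heritability, in (0, 1].
    P : DNA-test predictiveness, in (0, 1].
    """
    if not V_P > 0:
        raise ValueError(f"V_P must be positive, got {V_P}")
    if not 0 < H <= 1:
        raise ValueError(f"H must be in (0, 1], got {H}")
    if not 0 < P <= 1:
        raise ValueError(f"P must be in (0, 1], got {P}")
    V_G = H * V_P
    V_E = max(V_P - V_G, 0.0)
    V_M = P * V_G
    V_B = max(V_G - V_M, 0.0)
    return TraitTestScenario(
        scenario_id=scenario_id, H=H, P=P, V_P=V_P,
        V_G=V_G, V_E=V_E, V_M=V_M, V_B=V_B,
    )


def derive_a3(V_M: float, dominance_ratio: float) -> float:
    """Additive-effect scalar for the three-genotype population.

    Solves ``a3 = sqrt(4 * V_M / (2 + (d3/a3)^2))`` so that the 1:2:1 class
    distribution with means (a3, d3, -a3) has variance V_M.
    """
    if V_M < 0:
        raise ValueError(f"V_M must be non-negative, got {V_M}")
    if dominance_ratio < 0:
        raise ValueError(f"dominance ratio must be non-negative, got {dominance_ratio}")
    return math.sqrt(4.0 * V_M / (2.0 + dominance_ratio**2))


def derive_a9(V_M: float) -> float:
    """Effect scalar for the nine-genotype population.

    a9 is the positive scalar making the frequency-weighted variance of the
    nine class means equal V_M; the unit variance is enumerated once from the
    class table.
    """
    if V_M < 0:
        raise ValueError(f"V_M must be non-negative, got {V_M}")
    return math.sqrt(V_M / NINE_GENOTYPE_UNIT_VARIANCE)


def build_three_genotype_table(
    a3: float, dominance: str = "none"
) -> MarkerGenotypeTable:
    """Three-genotype class table with means (a3, d3, -a3), frequencies 1:2:1."""
    if a3 < 0:
        raise ValueError(f"a3 must be non-negative, got {a3}")
    try:
        ratio = DOMINANCE_RATIOS[dominance]
    except KeyError:
        raise ValueError(
            f"dominance must be one of {sorted(DOMINANCE_RATIOS)}, got {dominance!r}"
        ) from None
    d3 = ratio * a3
    return MarkerGenotypeTable(
        population_kind="three_genotype",
        dominance=dominance,
        zero_point=ZERO_POINT,
        labels=THREE_GENOTYPE_LABELS,
        frequencies=THREE_GENOTYPE_FREQUENCIES,
        means=(a3, d3, -a3),
        effect_scalar=a3,
    )


def build_nine_genotype_table(a9: float) -> MarkerGenotypeTable:
    """Nine-genotype class table for the epistatic two-locus population."""
    if a9 < 0:
        raise ValueError(f"a9 must be non-negative, got {a9}")
    return MarkerGenotypeTable(
        population_kind="nine_genotype",
        dominance=None,
        zero_point=ZERO_POINT,
        labels=NINE_GENOTYPE_LABELS,
        frequencies=NINE_GENOTYPE_FREQUENCIES,
        means=tuple(c * a9 for c in NINE_GENOTYPE_COEFFICIENTS),
        effect_scalar=a9,
    )


def marker_table_for(
    scenario: TraitTestScenario,
    population_kind: str,
    dominance: str | None = "none",
) -> MarkerGenotypeTable:
    """Build the marker-genotype table matching a scenario's V_M."""
    if population_kind == "three_genotype":
        dom = "none" if dominance is None else dominance
        a3 = derive_a3(scenario.V_M, DOMINANCE_RATIOS[dom])
        return build_three_genotype_table(a3, dom)
    if population_kind == "nine_genotype":
        return build_nine_genotype_table(derive_a9(scenario.V_M))
    raise ValueError(
        "population_kind must be 'three_genotype' or 'nine_genotype', "
        f"got {population_kind!r}"
    )


def scenario_grid(
    V_P: float = DEFAULT_V_P,
    H_levels=H_LEVELS,
    P_levels=P_LEVELS,
) -> list[TraitTestScenario]:
    """All (H, P) scenarios, H outer and P inner, ids starting at 1."""
    scenarios = []
    sid = 1
    for H in H_levels:
        for P in P_levels:
            scenarios.append(partition_variance(V_P, H, P, scenario_id=sid))
            sid += 1
    return scenarios


def table1_frame(
    scenarios: list[TraitTestScenario] | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Scenario grid with derived effect scalars, one row per scenario.

    Columns: scenario_id, H, P, V_P, V_G, V_E, V_M, V_B, a3_d0, a3_dhalf,
    a3_dfull, a9.  With ``decimals`` the derived-effect columns are rounded
    for display (the study's tables print them to one decimal).
    """
    if scenarios is None:
        scenarios = scenario_grid()
    rows = []
    for s in scenarios:
        row = {
            "scenario_id": s.scenario_id,
            "H": s.H, "P": s.P, "V_P": s.V_P,
            "V_G": s.V_G, "V_E": s.V_E, "V_M": s.V_M, "V_B": s.V_B,
            "a3_d0": derive_a3(s.V_M, DOMINANCE_RATIOS["none"]),
            "a3_dhalf": derive_a3(s.V_M, DOMINANCE_RATIOS["partial"]),
            "a3_dfull": derive_a3(s.V_M, DOMINANCE_RATIOS["complete"]),
            "a9": derive_a9(s.V_M),
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    if decimals is not None:
        for col in ("a3_d0", "a3_dhalf", "a3_dfull", "a9"):
            frame[col] = frame[col].round(decimals)
    return frame
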