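"""Closed-form genetic-gain predictions.

Phenotype-only gain uses the breeder's-equation form ``H * i(TSP) * sqrt(V_P)``
with ``i`` the truncated-standard-normal selection intensity.  Marker-only
gain is computed exactly by enumerating the discrete marker-class distribution
(fractionally thinning the boundary class, which leaves its mean unchanged —
the reason random within-class culling is unbiased), with a normal
approximation ``i(TSP) * sqrt(V_M)`` available for smoother distributions.
Two-stage gain adds the stage-1 exact marker gain to a stage-2
breeder's-equation term computed on the truncated distribution
(``H' = (V_M' + V_B) / (V_M' + V_B + V_E)``).  Index gain follows the
Lande–Thompson form with broad-sense heritability,

    dg_index = H * i(TSP) * sqrt(V_P) * sqrt(P/H + (1-P)^2 / (1 - H*P)).

These are infinite-population expectations; finite-N discreteness and
non-normal phenotype mixtures are the approximation gaps the simulator
quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetic_model import MarkerGenotypeTable


def selection_intensity(p: float) -> float:
    """Standard-normal truncation intensity i(p) = phi(Phi^-1(1-p)) / p.

    The mean, in standard-deviation units, of the retained upper tail when a
    proportion p of a standard normal is kept.  Decreasing in p; i(1) = 0.
    """
    if not 0 < p <= 1:
        raise ValueError(f"selection proportion must be in (0, 1], got {p}")
    threshold = stats.norm.isf(p)
    return float(stats.norm.pdf(threshold) / p)


def gain_phenotype_only(H: float, V_P: float, tsp: float) -> float:
    """Expected gain from phenotypic truncation: H * i(TSP) * sqrt(V_P)."""
    if not 0 < H <= 1:
        raise ValueError(f"H must be in (0, 1], got {H}")
    if V_P < 0:
        raise ValueError(f"V_P must be non-negative, got {V_P}")
    return H * selection_intensity(tsp) * math.sqrt(V_P)


@dataclass(frozen=True)
class TruncatedMarkerDistribution:
    """Marker-class distribution after truncation from above at SP_M."""

    labels: tuple[str, ...]
    frequencies: tuple[float, ...]  # renormalized; sum to 1
    means: tuple[float, ...]
    mean: float  # M'
    variance: float  # V_M'
    boundary_label: str | None  # partially retained class, if any
    boundary_retained_fraction: float  # fraction of that class kept


def truncate_marker_distribution(
    table: MarkerGenotypeTable, sp_m: float
) -> TruncatedMarkerDistribution:
    """Keep the best-mean proportion sp_m of the marker distribution.

    Classes are taken in descending order of mean; the boundary class is
    fractionally thinned (its mean is unchanged, its frequency scaled).
    """
    if not 0 < sp_m <= 1:
        raise ValueError(f"SP_M must be in (0, 1], got {sp_m}")
    means = table.means_array
    freqs = table.frequencies_array
    order = np.argsort(-means, kind="stable")

    labels, kept_freqs, kept_means = [], [], []
    boundary_label = None
    boundary_fraction = 1.0
    remaining = sp_m
    for idx in order:
        if remaining <= 1e-12:
            break
        take = min(freqs[idx], remaining)
        labels.append(table.labels[idx])
        kept_freqs.append(take / sp_m)
        kept_means.append(float(means[idx]))
        if take < freqs[idx] - 1e-12:
            boundary_label = table.labels[idx]
            boundary_fraction = take / freqs[idx]
        remaining -= take

    f = np.asarray(kept_freqs)
    v = np.asarray(kept_means)
    m_prime = float(f @ v)
    v_prime = max(float(f @ (v * v) - m_prime * m_prime), 0.0)
    return TruncatedMarkerDistribution(
        labels=tuple(labels),
        frequencies=tuple(float(x) for x in f),
        means=tuple(float(x) for x in v),
        mean=m_prime,
        variance=v_prime,
        boundary_label=boundary_label,
        boundary_retained_fraction=float(boundary_fraction),
    )


def gain_marker_only_exact(table: MarkerGenotypeTable, tsp: float) -> float:
    """Exact expected marker-only gain M' - M by class enumeration."""
    truncated = truncate_marker_distribution(table, tsp)
    return truncated.mean - table.mean()


def gain_marker_only_normal(V_M: float, tsp: float) -> float:
    """Normal-approximation marker-only gain i(TSP) * sqrt(V_M)."""
    if V_M < 0:
        raise ValueError(f"V_M must be non-negative, got {V_M}")
    return selection_intensity(tsp) * math.sqrt(V_M)


def gain_two_stage(
    table: MarkerGenotypeTable,
    V_B: float,
    V_E: float,
    tsp: float,
    sp_m: float,
) -> float:
    """Expected two-stage gain: exact stage-1 truncation + stage-2 response.

    Stage 2 applies the breeder's equation with post-truncation heritability
    H' and phenotypic variance V_P' = V_M' + V_B + V_E at intensity
    i(TSP/SP_M).
    """
    if V_B < 0 or V_E < 0:
        raise ValueError("V_B and V_E must be non-negative")
    if sp_m < tsp - 1e-12:
        raise ValueError(f"SP_M ({sp_m}) must be at least TSP ({tsp})")
    truncated = truncate_marker_distribution(table, sp_m)
    delta_g1 = truncated.mean - table.mean()
    V_P_prime = truncated.variance + V_B + V_E
    if V_P_prime <= 0:
        return delta_g1  # no residual variance, no second-stage response
    H_prime = (truncated.variance + V_B) / V_P_prime
    sp_p = min(tsp / sp_m, 1.0)
    return delta_g1 + H_prime * selection_intensity(sp_p) * math.sqrt(V_P_prime)


def optimal_two_stage(
    table: MarkerGenotypeTable,
    V_B: float,
    V_E: float,
    tsp: float,
    spm_grid,
) -> tuple[float, float]:
    """Grid argmax of the two-stage gain; ties go to the largest SP_M."""
    spm_grid = list(spm_grid)
    if not spm_grid:
        raise ValueError("SP_M grid is empty")
    best_spm, best_gain = None, -math.inf
    for sp_m in sorted(spm_grid):
        gain = gain_two_stage(table, V_B, V_E, tsp, sp_m)
        if gain >= best_gain:
            best_spm, best_gain = sp_m, gain
    return best_spm, best_gain


def gain_index(H: float, P: float, V_P: float, tsp: float) -> float:
    """Expected index gain (Lande–Thompson form with broad-sense H).

    The bracket P/H + (1-P)^2/(1-H*P) is at least max(1, P/H), so the index
    never predicts below phenotype-only or the normal-approximation
    marker-only gain.  At H = P = 1 the bracket limit is 1.
    """
    if not 0 < H <= 1:
        raise ValueError(f"H must be in (0, 1], got {H}")
    if not 0 <= P <= 1:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if V_P < 0:
        raise ValueError(f"V_P must be non-negative, got {V_P}")
    if H == 1 and P == 1:
        bracket = 1.0
    else:
        bracket = P / H + (1.0 - P) ** 2 / (1.0 - H * P)
    return H * selection_intensity(tsp) * math.sqrt(V_P) * math.sqrt(bracket)
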