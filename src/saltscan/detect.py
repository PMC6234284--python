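"""Detection limits for rare aquatic populations and the drift barrier.

Amplicon surveys sample a vanishing fraction of the cells in a water body.
If sequencing is proportional to cell abundance, the number of reads drawn
from a population at density rho in a community of density rho_c follows a
binomial with N = library size and p = rho / rho_c.  A population at one
cell per ml in a half-million-cells-per-ml community is missed entirely by
a 150,000-read library about 74% of the time, yet can number billions of
cells in a small lake — the census-size arithmetic this module also exposes.

The establishment side uses the classic branching-process result: a variant
with selective advantage s escapes stochastic loss with probability ~2s, so
it must appear on average 1/(2s) independent times before establishing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ML_PER_CUBIC_METER = 1e6


@dataclass
class DetectionParams:
    """Densities (cells/ml), library size (reads), and optional volume terms."""

    population_density: float
    community_density: float
    library_size: int
    area_m2: float | None = None
    depth_m: float | None = None

    def __post_init__(self) -> None:
        if self.community_density <= 0:
            raise ValueError("community density must be positive")
        if self.population_density < 0:
            raise ValueError("population density must be non-negative")
        if self.population_density > self.community_density:
            raise ValueError("population density cannot exceed community density")
        if self.library_size < 1:
            raise ValueError("library size must be >= 1")

    @property
    def read_probability(self) -> float:
        return self.population_density / self.community_density


def detection_probability(params: DetectionParams, k: int) -> float:
    """Binomial probability of observing exactly k reads from the population."""
    if not 0 <= k <= params.library_size:
        raise ValueError("k must lie in [0, library_size]")
    p = params.read_probability
    if p > 1:
        raise ValueError("per-read probability exceeds 1")
    return float(stats.binom.pmf(k, params.library_size, p))


def detection_probability_poisson(params: DetectionParams, k: int) -> float:
    """Poisson approximation e^(-Np) (Np)^k / k!; matches the binomial to
    four decimals whenever p < 1e-4."""
    if not 0 <= k <= params.library_size:
        raise ValueError("k must lie in [0, library_size]")
    lam = params.library_size * params.read_probability
    return float(stats.poisson.pmf(k, lam))


def establishment_appearances(s: float) -> float:
    """Expected independent appearances of a variant before establishment.

    Establishment probability per appearance is ~2s for a selective
    advantage s, so the expected number of appearances is 1/(2s): five for a
    10% advantage, five hundred for a 0.1% advantage.
    """
    if not 0 < s <= 1:
        raise ValueError("selective advantage must lie in (0, 1]")
    return 1.0 / (2.0 * s)


def census_size(params: DetectionParams) -> float:
    """Cells in a water layer: density x 1e6 ml/m^3 x area x depth."""
    if params.area_m2 is None or params.depth_m is None:
        raise ValueError("census size needs area_m2 and depth_m")
    if params.area_m2 <= 0 or params.depth_m <= 0:
        raise ValueError("area and depth must be positive")
    if params.population_density <= 0:
        raise ValueError("population density must be positive for a census")
    return params.population_density * ML_PER_CUBIC_METER * params.area_m2 * params.depth_m
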