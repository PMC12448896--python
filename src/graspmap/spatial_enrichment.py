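"""Spatial enrichment of neuron classes within movement representations.

Two questions are asked of the overlap between the neuron maps and the
ICMS-derived movement representations: (1) do the fractions of
outcome-independent vs outcome-dependent neurons differ across
representations (Pearson chi-square with Cramer's V effect size), and
(2) is the neuron density (neurons per gridpoint of representation area)
inside a given representation higher or lower than expected if neurons
were placed uniformly at random on the electrode grid (Monte Carlo null,
two-tailed empirical p with an add-one correction so p is never 0)?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cortical_maps import Representation, nearest_gridpoint_index
from .synthgen import GridSpec

__all__ = [
    "EnrichmentResult",
    "count_in_representation",
    "chi_square_classes",
    "cramers_v",
    "monte_carlo_null",
    "normalized_histogram",
]


@dataclass
class EnrichmentResult:
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float
    cramers_v: float
    per_representation: pd.DataFrame
    null_samples: dict[str, np.ndarray] = field(default_factory=dict)
    n_sim: int = 0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.cramers_v <= 1.0 + 1e-12:
            raise ValueError("Cramer's V must lie in [0, 1]")


class EmptyRepresentationError(ValueError):
    pass


def count_in_representation(
    positions: list[tuple[float, float]],
    representation: Representation,
) -> tuple[int, float]:
    """Neurons whose nearest gridpoint lies in the mask, and their density.

    Density is count per gridpoint of representation area; a neuron under
    several overlapping representations counts in each.
    """
    if representation.area == 0:
        raise EmptyRepresentationError(
            f"representation {representation.movement_class!r} has zero area"
        )
    count = 0
    for pos in positions:
        i, j = nearest_gridpoint_index(pos, representation.grid)
        if representation.mask[i, j]:
            count += 1
    return count, count / representation.area


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramer's V = sqrt(chi2 / (N * (min(r, c) - 1)))."""
    if min(r, c) < 2:
        raise ValueError("V needs at least a 2x2 table")
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def chi_square_classes(
    contingency: pd.DataFrame,
) -> tuple[float, int, float, float]:
    """Pearson chi-square (no continuity correction) and Cramer's V.

    Rows are neuron classes, columns movement representations. All
    marginals must be positive.
    """
    table = contingency.to_numpy(dtype=float)
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("degenerate table: zero marginal")
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    v = cramers_v(chi2, int(table.sum()), *table.shape)
    return float(chi2), int(dof), float(p), v


def monte_carlo_null(
    n_neurons: int,
    grid: GridSpec,
    representation: Representation,
    observed_density: float | None = None,
    n_sim: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    tail: str = "absolute",
) -> tuple[np.ndarray, float | None]:
    """Uniform-placement null for the in-representation neuron density.

    Each simulation drops ``n_neurons`` independently and uniformly (with
    replacement) on the gridpoints and records the density inside the
    representation. The two-tailed empirical p for ``observed_density`` is
    (1 + #{|d - mean(null)| >= |d_obs - mean(null)|}) / (1 + n_sim) with
    ``tail="absolute"`` (default), or the doubled smaller tail with
    ``tail="double"``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    area = representation.area
    if area == 0:
        raise EmptyRepresentationError("representation covers zero gridpoints")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_points = grid.n_points
    in_mask = representation.mask.ravel()  # ML-major, matches gridpoints()
    draws = rng.integers(0, n_points, size=(n_sim, n_neurons))
    null = in_mask[draws].sum(axis=1) / area

    p = None
    if observed_density is not None:
        center = null.mean()
        if tail == "absolute":
            extreme = np.abs(null - center) >= abs(observed_density - center) - 1e-12
            p = (1 + int(extreme.sum())) / (1 + n_sim)
        elif tail == "double":
            hi = (1 + int((null >= observed_density - 1e-12).sum())) / (1 + n_sim)
            lo = (1 + int((null <= observed_density + 1e-12).sum())) / (1 + n_sim)
            p = min(1.0, 2 * min(hi, lo))
        else:
            raise ValueError(f"unknown tail convention {tail!r}")
    return null, p


def normalized_histogram(
    samples: np.ndarray, n_bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram normalized so total area integrates to one.

    Bar height = fraction in bin / bin width (a probability density, so
    heights may exceed one). Returns (heights, bin_edges).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    lo, hi = samples.min(), samples.max()
    if hi == lo:  # all samples identical: one unit-area bar
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("zero-width bins")
    heights, edges = np.histogram(samples, bins=edges, density=True)
    return heights, edges


def enrichment_analysis(
    positions_by_class: dict[str, list[tuple[float, float]]],
    representations: list[Representation],
    grid: GridSpec,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> dict[str, EnrichmentResult]:
    """Full enrichment report: one chi-square over the representation set
    and one Monte Carlo density test per (class, representation) pair."""
    counts = {
        cls: {
            rep.movement_class: count_in_representation(pos, rep)[0]
            for rep in representations
        }
        for cls, pos in positions_by_class.items()
    }
    contingency = pd.DataFrame(counts).T  # rows: classes, cols: representations
    chi2, dof, p, v = chi_square_classes(contingency)

    out: dict[str, EnrichmentResult] = {}
    rng = np.random.default_rng(seed)
    for cls, positions in positions_by_class.items():
        rows = []
        nulls = {}
        for rep in representations:
            count, density = count_in_representation(positions, rep)
            null, p_mc = monte_carlo_null(
                len(positions), grid, rep,
                observed_density=density, n_sim=n_sim, rng=rng,
            )
            nulls[rep.movement_class] = null
            rows.append(
                {
                    "representation": rep.movement_class,
                    "area_gridpoints": rep.area,
                    "observed_count": count,
                    "observed_density": density,
                    "null_mean": null.mean(),
                    "p_empirical": p_mc,
                }
            )
        out[cls] = EnrichmentResult(
            contingency=contingency,
            chi2=chi2,
            df=dof,
            p=p,
            cramers_v=v,
            per_representation=pd.DataFrame(rows),
            null_samples=nulls,
            n_sim=n_sim,
            seed=seed,
        )
    return out
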