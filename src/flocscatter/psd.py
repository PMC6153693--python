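"""Particle-size-distribution post-processing.

Laser granulometers report binned distributions of the equivalent diameter
d_i on a log grid, weighted either by particle volume, f(v_i), or by particle
count, f(n_i).  The two views of the same suspension differ dramatically for
activated sludge: volume is dominated by ~100 um flocs while number is
dominated by the 2-10 um microfloc population.  The bridge between them is
the cubic rule n_i ~ v_i / d_i^3 (a sphere's volume scales as d^3), applied
per bin with renormalization.

The module also handles flat per-particle diameter lists, the form image
analyzers produce: size-band counting and min/max summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDistributionError, DomainError

__all__ = [
    "SizeGrid",
    "SizeDistribution",
    "ParticleList",
    "reweight",
    "fraction_between",
    "percentile_diameter",
    "band_counts",
    "summary_stats",
    "BasisConverter",
]

VALID_BASES = ("volume", "number")


@dataclass(frozen=True)
class SizeGrid:
    """Bin edges in um, strictly increasing and positive.

    The representative diameter of a bin is the geometric mean of its edges —
    the natural centroid on a log-uniform grid where bins span decades.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise DomainError("SizeGrid needs a 1-D array of >= 2 edges")
        if not np.all(edges > 0):
            raise DomainError("bin edges must be positive")
        if not np.all(np.diff(edges) > 0):
            raise DomainError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def default(cls, d_min: float = 0.02, d_max: float = 2000.0,
                n_bins: int = 100) -> "SizeGrid":
        """Log-uniform grid over the granulometer's 0.02-2000 um span."""
        if not (0 < d_min < d_max):
            raise DomainError("need 0 < d_min < d_max")
        return cls(np.logspace(np.log10(d_min), np.log10(d_max), n_bins + 1))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def representative(self) -> np.ndarray:
        """Geometric mean of each bin's edges (um)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def log_widths(self) -> np.ndarray:
        return np.diff(np.log(self.edges))


@dataclass(frozen=True)
class SizeDistribution:
    """Binned PSD: nonnegative per-bin fractions summing to 1, with an
    explicit basis (``"volume"`` or ``"number"``)."""

    grid: SizeGrid
    weights: np.ndarray
    basis: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.n_bins,):
            raise DomainError(
                f"weights must have length {self.grid.n_bins} (one per bin)"
            )
        if np.any(w < 0):
            raise DomainError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise DomainError("weights must sum to 1 (within 1e-9)")
        if self.basis not in VALID_BASES:
            raise DomainError(f"basis must be one of {VALID_BASES}")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_weights(cls, grid: SizeGrid, weights, basis: str,
                     normalize: bool = True) -> "SizeDistribution":
        w = np.asarray(weights, dtype=float)
        if normalize:
            total = w.sum()
            if total <= 0:
                raise DegenerateDistributionError(
                    "cannot normalize a distribution with zero total weight"
                )
            w = w / total
        return cls(grid, w, basis)


@dataclass(frozen=True)
class ParticleList:
    """Flat list of equivalent-circle diameters in um (image-analysis style)."""

    diameters: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float).reshape(-1)
        if d.size and not np.all(d > 0):
            raise DomainError("all diameters must be positive")
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return self.diameters.size


def reweight(dist: SizeDistribution, target_basis: str) -> SizeDistribution:
    """Convert between volume and number bases on a shared grid.

    Volume -> number divides each bin weight by d_i^3 (d_i the representative
    diameter) and renormalizes; number -> volume multiplies by d_i^3.  The two
    directions are exact inverses, so round-trips reproduce the input.
    """
    if target_basis not in VALID_BASES:
        raise DomainError(f"target basis must be one of {VALID_BASES}")
    if target_basis == dist.basis:
        return SizeDistribution(dist.grid, dist.weights.copy(), dist.basis)
    d3 = dist.grid.representative ** 3
    raw = dist.weights / d3 if target_basis == "number" else dist.weights * d3
    total = raw.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            "conversion produced zero total weight"
        )
    return SizeDistribution(dist.grid, raw / total, target_basis)


def fraction_between(dist: SizeDistribution, d_lo: float,
                     d_hi: float) -> float:
    """Weight fraction in the diameter range [d_lo, d_hi).

    Bins fully inside contribute their whole weight; bins straddling a cut
    contribute pro-rata by log-width (instrument bin edges need not coincide
    with reporting cuts such as 10 um).  Fractions over a partition of the
    grid sum to 1.
    """
    if not d_lo < d_hi:
        raise DomainError("need d_lo < d_hi")
    lo = np.log(max(d_lo, dist.grid.edges[0]))
    hi = np.log(min(d_hi, dist.grid.edges[-1]))
    if hi <= lo:
        return 0.0
    le = np.log(dist.grid.edges)
    overlap = np.minimum(le[1:], hi) - np.maximum(le[:-1], lo)
    frac = np.clip(overlap, 0.0, None) / dist.grid.log_widths
    return float(np.clip((dist.weights * frac).sum(), 0.0, 1.0))


def percentile_diameter(dist: SizeDistribution, p: float) -> float:
    """Diameter (um) at which the cumulative weight reaches fraction ``p``.

    The cumulative is interpolated log-linearly within bins (weight uniform
    in log d inside each bin), so d50 of a symmetric log distribution is its
    geometric centre.  Monotone in p.
    """
    if not (0.0 < p < 1.0):
        raise DomainError("percentile fraction p must lie in (0, 1)")
    w = dist.weights
    if w.sum() <= 0:
        raise DegenerateDistributionError("all-zero distribution")
    cum = np.concatenate([[0.0], np.cumsum(w)])
    cum /= cum[-1]
    j = int(np.searchsorted(cum, p))  # first edge index with cum[j] >= p
    k = j - 1  # bin holding percentile p; w[k] > 0 since cum[k] < p <= cum[k+1]
    frac = (p - cum[k]) / w[k]
    le = np.log(dist.grid.edges)
    return float(np.exp(le[k] + frac * (le[k + 1] - le[k])))


def band_counts(particles: ParticleList, band_edges) -> np.ndarray:
    """Count particles per size band.

    ``band_edges`` (strictly increasing, um) define half-open bands
    [e_k, e_{k+1}) plus the open-ended bands below the first and at/above the
    last edge; counts always sum to the list length.
    """
    edges = np.asarray(band_edges, dtype=float).reshape(-1)
    if edges.size < 1:
        raise DomainError("need at least one band edge")
    if edges.size > 1 and not np.all(np.diff(edges) > 0):
        raise DomainError("band edges must be strictly increasing")
    idx = np.searchsorted(edges, particles.diameters, side="right")
    return np.bincount(idx, minlength=edges.size + 1)


def summary_stats(particles: ParticleList) -> dict:
    """Exact min/max diameter (um) and particle count of a non-empty list."""
    if len(particles) == 0:
        raise DomainError("cannot summarize an empty particle list")
    d = particles.diameters
    return {"min_um": float(d.min()), "max_um": float(d.max()),
            "count": int(d.size)}


class BasisConverter(TransformerMixin, BaseEstimator):
    """Transformer converting PSD weight vectors between bases.

    Operates on raw weight arrays of shape ``(n_bins,)`` or
    ``(n_samples, n_bins)`` tied to a fixed :class:`SizeGrid`, so it composes
    with sklearn pipelines; :func:`reweight` is the object-level equivalent.

    Parameters
    ----------
    grid : SizeGrid
        Shared bin grid of the input rows.
    source_basis, target_basis : {"volume", "number"}
        Basis of the input rows and of the output.
    """

    def __init__(self, grid: SizeGrid, source_basis: str = "volume",
                 target_basis: str = "number"):
        self.grid = grid
        self.source_basis = source_basis
        self.target_basis = target_basis

    def fit(self, X=None, y=None):
        if self.source_basis not in VALID_BASES \
                or self.target_basis not in VALID_BASES:
            raise DomainError(f"bases must be one of {VALID_BASES}")
        return self

    def transform(self, X):
        self.fit()
        W = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(W)
        for i, row in enumerate(W):
            dist = SizeDistribution.from_weights(self.grid, row,
                                                 self.source_basis)
            out[i] = reweight(dist, self.target_basis).weights
        return out[0] if np.asarray(X).ndim == 1 else out
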