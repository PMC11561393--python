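"""Discrete latent-ability distributions on a rectangular quadrature grid.

Marginal maximum likelihood integrates ability out over a grid of equally
spaced nodes θ_1..θ_K carrying probability weights w_1..w_K.  "Rectangular"
quadrature means equally spaced nodes with density-proportional weights
(midpoint rule), not Gauss–Hermite; the default grid is 49 points on
[−6, 6].  The weights may be normal-density based or estimated as an
empirical histogram during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["LatentDist", "make_quadrature", "dist_moments", "update_empirical_histogram"]


@dataclass(frozen=True)
class LatentDist:
    """Nodes and weights of a discrete latent distribution."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must have positive finite total mass")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    @property
    def mu(self) -> float:
        return float(self.weights @ self.nodes)

    @property
    def sigma2(self) -> float:
        return float(self.weights @ (self.nodes - self.mu) ** 2)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def to_frame(self):
        """Two-column (theta, weight) table."""
        import pandas as pd

        return pd.DataFrame({"theta": self.nodes, "weight": self.weights})


def make_quadrature(
    n_points: int = 49,
    bound: float = 6.0,
    mean: float = 0.0,
    sd: float = 1.0,
) -> LatentDist:
    """Equally spaced nodes on [−bound, bound] with weights proportional to
    the N(mean, sd²) density at the nodes, renormalized to sum to 1.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    if bound <= 0:
        raise ValueError("bound must be positive")
    nodes = np.linspace(-bound, bound, n_points)
    weights = norm.pdf(nodes, loc=mean, scale=sd)
    return LatentDist(nodes, weights)


def dist_moments(dist: LatentDist) -> tuple[float, float, float]:
    """(mu, sigma2, sigma) of a discrete latent distribution."""
    return dist.mu, dist.sigma2, dist.sigma


def update_empirical_histogram(
    dist: LatentDist,
    posterior_mass: np.ndarray,
    standardize: bool = False,
) -> LatentDist:
    """Replace the weights by normalized posterior mass (empirical histogram).

    With ``standardize`` the updated distribution is rescaled to mean 0 and
    variance 1: nodes are linearly transformed and the mass re-interpolated
    onto the original grid.  Plain calibration standardizes each cycle so the
    N(0, 1) identification of the θ scale is preserved; fixed-item
    calibration must NOT standardize (the fixed items identify the scale).
    """
    mass = np.asarray(posterior_mass, dtype=float)
    if mass.shape != dist.nodes.shape:
        raise ValueError("posterior_mass must match the node grid")
    if (mass < 0).any():
        raise ValueError("posterior_mass must be non-negative")
    total = mass.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("posterior_mass has no usable mass")
    w = mass / total
    if not standardize:
        return LatentDist(dist.nodes, w)
    mu = w @ dist.nodes
    sigma = np.sqrt(w @ (dist.nodes - mu) ** 2)
    if sigma <= 0:
        raise ValueError("degenerate posterior mass cannot be standardized")
    grid = dist.nodes

    def _regrid(shift: float, scale: float) -> np.ndarray:
        # mass sits at affinely transformed node positions; re-grid by
        # linear interpolation of the CDF onto the original grid cells
        new_nodes = (grid - shift) / scale
        cdf = np.concatenate([[0.0], np.cumsum(w)])
        half = np.diff(new_nodes) / 2.0
        edges = np.concatenate(
            [[new_nodes[0] - half[0]], new_nodes[:-1] + half, [new_nodes[-1] + half[-1]]]
        )
        gh = np.diff(grid) / 2.0
        grid_edges = np.concatenate(
            [[grid[0] - gh[0]], grid[:-1] + gh, [grid[-1] + gh[-1]]]
        )
        cdf_at = np.interp(grid_edges, edges, cdf, left=0.0, right=1.0)
        return np.maximum(np.diff(cdf_at), 0.0)

    # interpolation onto a coarse grid slightly inflates the variance, so
    # iterate the affine transform until the discrete moments are (0, 1)
    shift, scale = float(mu), float(sigma)
    new_w = _regrid(shift, scale)
    for _ in range(50):
        total = new_w.sum()
        if total <= 0:
            raise ValueError("standardization moved all mass off the grid")
        ww = new_w / total
        m = ww @ grid
        v = ww @ (grid - m) ** 2
        if abs(m) < 1e-9 and abs(v - 1.0) < 1e-9:
            break
        shift += m * scale
        scale *= np.sqrt(v)
        new_w = _regrid(shift, scale)
    return LatentDist(grid, new_w)
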