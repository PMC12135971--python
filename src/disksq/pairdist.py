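"""Pair distribution function g(r) from disk configurations.

Pairs are counted inside the circle of diameter l inscribed in the periodic
box, with direct (non-periodic) distances; the finite, non-uniform geometry
is divided out exactly using the analytic density of the distance between
two independent uniform points in a disk.  This sidesteps the usual
shell-volume edge corrections and yields g(r) over the full [0, l] range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import pair_distance_counts
from .packing import DiskConfiguration

__all__ = [
    "DistanceHistogram",
    "PairDistribution",
    "pair_distance_histogram",
    "circle_distance_density",
    "expected_bin_fractions",
    "normalize_to_pdf",
    "average_pdfs",
]

#: bins with expected fraction below this are unreliable and yield g = 0
N_I_FLOOR = 1e-12


@dataclass
class DistanceHistogram:
    """Binned pair-distance counts of the disks inside the inscribed circle."""

    counts: np.ndarray      # per-bin pair counts, bin i = [i w_b, (i+1) w_b)
    bin_width: float        # w_b, radii
    n_bins: int             # N_b = round(l / w_b); r domain [0, l]
    l: float                # box side = circle diameter
    n0: int                 # disks found strictly inside the circle
    nu: float               # number density N / l^2 of the source config

    @property
    def n_pairs(self) -> int:
        return self.n0 * (self.n0 - 1) // 2

    @property
    def n_theory(self) -> float:
        """Expected disk count nu pi (l/2)^2, used instead of fluctuating n0."""
        return self.nu * np.pi * (self.l / 2.0) ** 2


@dataclass
class PairDistribution:
    """g(r) on bin centers; h(r) = g(r) - 1 is the correlation function."""

    r_grid: np.ndarray
    g: np.ndarray
    phi: float
    l: float
    n_samples: int = 1

    @property
    def h(self) -> np.ndarray:
        return self.g - 1.0

    @property
    def bin_width(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])


def pair_distance_histogram(config: DiskConfiguration,
                            w_b: float = 0.1) -> DistanceHistogram:
    """Histogram all pair distances of disks strictly inside radius l/2.

    Distances are direct Euclidean ones: the inscribed circle never wraps
    the periodic seam, so no minimum-image convention is applied.
    """
    l = config.l
    rel = config.positions - l / 2.0
    inside = np.hypot(rel[:, 0], rel[:, 1]) < l / 2.0
    pts = np.ascontiguousarray(config.positions[inside])
    if len(pts) < 2:
        raise ValueError(f"only {len(pts)} disks inside the circle; need >= 2")
    n_bins = int(round(l / w_b))
    counts = pair_distance_counts(pts, w_b, n_bins)
    return DistanceHistogram(
        counts=counts, bin_width=w_b, n_bins=n_bins, l=l,
        n0=len(pts), nu=config.nu,
    )


def circle_distance_density(x):
    """Density of the normalized distance x = r / (2R) between two uniform
    random points in a disk of radius R.

    rho(x) = (16 x / pi) (arccos x - x sqrt(1 - x^2)),  0 <= x <= 1,
    vanishing at both endpoints and integrating to 1.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("normalized distance x must lie in [0, 1]")
    return 16.0 * x / np.pi * (np.arccos(x) - x * np.sqrt(1.0 - x * x))


def expected_bin_fractions(n_bins: int) -> np.ndarray:
    """Expected fraction n_i of pairs per distance bin for uniform points.

    n_i = rho(x_i) * delta_r with x_i the bin-center normalized distance and
    delta_r = 1/N_b; the n_i sum to 1 up to midpoint-rule discretization.
    """
    if n_bins < 10:
        raise ValueError(f"n_bins={n_bins} too small (need >= 10)")
    x = (np.arange(n_bins) + 0.5) / n_bins
    return circle_distance_density(x) / n_bins


def normalize_to_pdf(hist: DistanceHistogram) -> PairDistribution:
    """g_i = p_i / n_i with p_i = counts_i / (Nbar (Nbar - 1) / 2).

    Nbar is the theoretical disk count in the circle (the measured count
    fluctuates sample to sample).  Bins whose expected fraction underflows
    are set to 0.
    """
    nbar = hist.n_theory
    pairs_theory = nbar * (nbar - 1.0) / 2.0
    p = hist.counts / pairs_theory
    n_i = expected_bin_fractions(hist.n_bins)
    g = np.zeros_like(p)
    ok = n_i > N_I_FLOOR
    g[ok] = p[ok] / n_i[ok]
    r = (np.arange(hist.n_bins) + 0.5) * hist.bin_width
    phi = hist.nu * np.pi
    return PairDistribution(r_grid=r, g=g, phi=phi, l=hist.l)


def average_pdfs(pdfs) -> PairDistribution:
    """Pointwise mean of pair distributions on identical grids."""
    pdfs = list(pdfs)
    if not pdfs:
        raise ValueError("no pair distributions to average")
    first = pdfs[0]
    for p in pdfs[1:]:
        if len(p.r_grid) != len(first.r_grid) or not np.allclose(p.r_grid, first.r_grid):
            raise ValueError("mismatched r grids")
        if abs(p.phi - first.phi) > 1e-12:
            raise ValueError("mismatched area fractions")
    g = np.mean([p.g for p in pdfs], axis=0)
    n = sum(p.n_samples for p in pdfs)
    return replace(first, g=g, n_samples=n)
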