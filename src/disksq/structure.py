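"""Structure factor S(Q) from g(r) by the discrete zero-order Hankel transform.

For a 2D isotropic system (or parallel cylinders viewed along the axis),
S(Q) = 1 + 2 pi nu  integral h(r) J0(Qr) r dr, with h = g - 1 and nu the
number density.  The integral is evaluated by the midpoint rule on the
histogram bin centers as a reusable matrix A[i, j] = r_j J0(Q_i r_j), so a
whole family of samples at fixed grids costs one matrix-vector product
each.  h is tapered linearly to zero between l/4 and l/2 to suppress
low-Q noise from the weakly sampled tail, and the noisy region below
Q = 0.6 is replaced by a Q^2-weighted parabolic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import j0

from .pairdist import PairDistribution

__all__ = [
    "StructureFactorCurve",
    "default_q_grid",
    "taper_correlation",
    "hankel_matrix",
    "structure_factor_from_pdf",
    "low_q_parabola_replace",
]


def default_q_grid(q_max: float = 10.0, q_step: float = 0.01) -> np.ndarray:
    """Uniform Q grid from 0 to q_max (QR scale, unit disk radius)."""
    n = int(round(q_max / q_step))
    return np.linspace(0.0, q_max, n + 1)


@dataclass
class StructureFactorCurve:
    """S on a uniform Q grid at one area fraction."""

    q_grid: np.ndarray
    s: np.ndarray
    phi: float
    r_max: float
    nu: float
    n_samples: int = 1

    def copy(self) -> "StructureFactorCurve":
        return replace(self, s=self.s.copy())


def taper_correlation(pdf: PairDistribution, l: float | None = None) -> np.ndarray:
    """h(r) = g(r) - 1 multiplied by a linear window: 1 up to l/4, ramping
    to 0 at l/2, 0 beyond.

    The window multiplies h rather than g; scaling g itself would leave
    h -> -1 at large r and destroy the S -> 1 limit.
    """
    if l is None:
        l = pdf.l
    r = pdf.r_grid
    w = np.clip((l / 2.0 - r) / (l / 4.0), 0.0, 1.0)
    return pdf.h * w


def hankel_matrix(q_grid, r_grid) -> np.ndarray:
    """A[i, j] = r_j J0(Q_i r_j); reusable across samples at fixed grids."""
    q = np.asarray(q_grid, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    return r * j0(np.outer(q, r))


def structure_factor_from_pdf(pdf: PairDistribution, q_grid=None,
                              r_max: float | None = None,
                              matrix: np.ndarray | None = None) -> StructureFactorCurve:
    """S(Q_i) = 1 + 2 pi nu dr sum_j h_j r_j J0(Q_i r_j) over r_j <= r_max.

    r_max defaults to l/2 (the inscribed-circle radius, beyond which the
    histogram has no support).  Passing a precomputed matrix for the full
    r grid lets callers truncate cheaply by slicing columns.
    """
    l = pdf.l
    if r_max is None:
        r_max = l / 2.0
    if r_max > l / 2.0 + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds l/2={l / 2.0}: no data beyond "
                         "the inscribed-circle radius")
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    dr = pdf.bin_width
    h = taper_correlation(pdf, l)
    m = int(np.searchsorted(pdf.r_grid, r_max, side="right"))
    if matrix is None:
        matrix = hankel_matrix(q_grid, pdf.r_grid[:m])
    nu = pdf.phi / np.pi
    s = 1.0 + 2.0 * np.pi * nu * dr * (matrix[:, :m] @ h[:m])
    return StructureFactorCurve(q_grid=q_grid, s=s, phi=pdf.phi, r_max=r_max,
                                nu=nu, n_samples=pdf.n_samples)


def low_q_parabola_replace(curve: StructureFactorCurve,
                           q_cut: float = 0.6) -> StructureFactorCurve:
    """Replace S on [0, q_cut] by a parabola fitted with weights ~ Q^2.

    The transform oscillates spuriously at very low Q (finite r_max); the
    fit uses the points in (0, q_cut] — the weight vanishes at Q = 0 — and
    the fitted c0 + c1 Q + c2 Q^2 overwrites S at Q <= q_cut.
    """
    q = curve.q_grid
    mask = (q > 0) & (q <= q_cut)
    if mask.sum() < 10:
        raise ValueError(f"only {int(mask.sum())} points below q_cut={q_cut}; need >= 10")
    qm = q[mask]
    w = qm  # sqrt of the Q^2 weights
    design = np.column_stack([np.ones_like(qm), qm, qm * qm]) * w[:, None]
    coeffs, *_ = np.linalg.lstsq(design, curve.s[mask] * w, rcond=None)
    s = curve.s.copy()
    rep = q <= q_cut
    s[rep] = coeffs[0] + coeffs[1] * q[rep] + coeffs[2] * q[rep] ** 2
    return replace(curve, s=s)
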