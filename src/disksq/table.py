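"""Smoothing, (phi, Q) tabulation and serialization of structure factors.

Per-density curves are smoothed with a Savitzky-Golay filter (window 29
grid points = 0.29 in Q, polynomial order 3) and assembled into a table
over the area-fraction grid; a bivariate degree-2 B-spline with unit
weights and smoothing factor 0.1 provides continuous evaluation in
(phi, Q).  The table serializes to a little-endian binary format with a
TSV mirror for interoperability.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import bisplev, bisplrep
from scipy.signal import peak_prominences, savgol_filter

from .structure import StructureFactorCurve

__all__ = [
    "StructureFactorTable",
    "TableFormatError",
    "smooth_curve",
    "fit_bivariate_spline",
    "evaluate_table",
    "locate_peaks",
    "principal_peaks",
    "write_table",
    "read_table",
]

_MAGIC = b"DISKSQTB"
_VERSION = 1


class TableFormatError(ValueError):
    """Malformed, truncated or wrong-version table file."""


def smooth_curve(curve: StructureFactorCurve, window: int = 29,
                 polyorder: int = 3) -> StructureFactorCurve:
    """Savitzky-Golay smoothing over the full Q range.

    Polynomials of degree <= polyorder pass through unchanged; the window
    must be odd and exceed the polynomial order.
    """
    if window % 2 == 0:
        raise ValueError(f"window={window} must be odd")
    if window <= polyorder:
        raise ValueError(f"window={window} must exceed polyorder={polyorder}")
    if len(curve.s) <= window:
        raise ValueError(f"curve has {len(curve.s)} points <= window={window}")
    s = savgol_filter(curve.s, window_length=window, polyorder=polyorder)
    return StructureFactorCurve(q_grid=curve.q_grid, s=s, phi=curve.phi,
                                r_max=curve.r_max, nu=curve.nu,
                                n_samples=curve.n_samples)


@dataclass
class StructureFactorTable:
    """S(phi, Q) on a rectangular grid plus its bivariate spline."""

    phi_grid: np.ndarray      # ascending area fractions
    q_grid: np.ndarray        # ascending Q (QR scale)
    values: np.ndarray        # (n_phi, n_q) smoothed S
    tck: tuple                # (tx, ty, c, kx, ky) from bisplrep
    provenance: list | None = None  # per-row metadata dicts

    def evaluate(self, phi, q):
        return evaluate_table(self, phi, q)


def fit_bivariate_spline(curves, smoothing: float = 0.1,
                         degree: int = 2,
                         provenance: list | None = None) -> StructureFactorTable:
    """Fit a degree-2 smoothing B-spline in (phi, Q) through per-phi curves.

    All curves must share the Q grid; weights are unity and the smoothing
    factor (total squared residual allowance) defaults to 0.1.  At least 4
    area-fraction rows are required.
    """
    curves = sorted(curves, key=lambda c: c.phi)
    if len(curves) < 4:
        raise ValueError(f"need >= 4 area-fraction rows, got {len(curves)}")
    q = curves[0].q_grid
    for c in curves[1:]:
        if len(c.q_grid) != len(q) or not np.allclose(c.q_grid, q):
            raise ValueError("curves are not on a common Q grid")
    phi = np.array([c.phi for c in curves])
    if np.any(np.diff(phi) <= 0):
        raise ValueError("duplicate area fractions")
    values = np.vstack([c.s for c in curves])
    pp, qq = np.meshgrid(phi, q, indexing="ij")
    tck = bisplrep(pp.ravel(), qq.ravel(), values.ravel(),
                   kx=degree, ky=degree, s=smoothing)
    return StructureFactorTable(phi_grid=phi, q_grid=q.copy(), values=values,
                                tck=tuple(tck), provenance=provenance)


def evaluate_table(table: StructureFactorTable, phi, q):
    """Spline evaluation S(phi, q); out-of-range requests are rejected.

    phi and q may be scalars or arrays; arrays are evaluated pointwise on
    the broadcast shape of (phi, q) when both are arrays of equal length,
    or on the grid q for scalar phi.
    """
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    lo_p, hi_p = table.phi_grid[0], table.phi_grid[-1]
    lo_q, hi_q = table.q_grid[0], table.q_grid[-1]
    if np.any((phi_arr < lo_p - 1e-12) | (phi_arr > hi_p + 1e-12)):
        raise ValueError(f"phi out of tabulated range [{lo_p}, {hi_p}]")
    if np.any((q_arr < lo_q - 1e-12) | (q_arr > hi_q + 1e-12)):
        raise ValueError(f"q out of tabulated range [{lo_q}, {hi_q}]")
    if phi_arr.size == 1:
        order = np.argsort(q_arr)
        out = np.asarray(bisplev(phi_arr, q_arr[order], table.tck)).ravel()
        res = np.empty_like(out)
        res[order] = out
        return float(res[0]) if np.isscalar(q) or np.asarray(q).ndim == 0 else res
    # pointwise (phi_i, q_i)
    if phi_arr.shape != q_arr.shape:
        raise ValueError("phi and q arrays must have matching shapes")
    res = np.array([bisplev(p, x, table.tck) for p, x in zip(phi_arr, q_arr)])
    return res


def locate_peaks(curve_or_q, s=None, q_window=None, min_prominence: float = 0.0):
    """Local maxima of S(Q) by three-point comparison, refined by fitting a
    parabola through the three bracketing samples.

    Accepts a StructureFactorCurve or (q, s) arrays.  q_window restricts
    the search range; min_prominence (scipy peak prominence) filters noise
    bumps.  Returns [(q_peak, s_peak), ...] in ascending Q.
    """
    if s is None:
        q, s = curve_or_q.q_grid, curve_or_q.s
    else:
        q = np.asarray(curve_or_q, dtype=float)
        s = np.asarray(s, dtype=float)
    idx = np.flatnonzero((s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])) + 1
    if q_window is not None:
        lo, hi = q_window
        idx = idx[(q[idx] >= lo) & (q[idx] <= hi)]
    if min_prominence > 0 and len(idx):
        prom = peak_prominences(s, idx)[0]
        idx = idx[prom >= min_prominence]
    peaks = []
    for i in idx:
        s0, s1, s2 = s[i - 1], s[i], s[i + 1]
        denom = s0 - 2.0 * s1 + s2
        delta = 0.0 if denom == 0 else 0.5 * (s0 - s2) / denom
        dq = q[i + 1] - q[i]
        peaks.append((float(q[i] + delta * dq),
                      float(s1 - 0.25 * (s0 - s2) * delta)))
    return peaks


def principal_peaks(curve, n: int = 3, q_window=(1.5, 8.0),
                    min_separation: float = 0.5):
    """The n dominant diffraction-like peaks of a curve, in ascending Q.

    Local maxima are ranked by height and accepted greedily, skipping any
    candidate closer than min_separation to an already accepted peak; this
    rejects the truncation sidelobes that flank sharp peaks (spacing
    ~ pi / r_max) while the physical peaks of dense packings are well
    separated (>= 0.85 on the QR scale for hexagonal-like order).
    """
    cands = sorted(locate_peaks(curve, q_window=q_window),
                   key=lambda p: -p[1])
    kept = []
    for qp, sp in cands:
        if all(abs(qp - k[0]) >= min_separation for k in kept):
            kept.append((qp, sp))
        if len(kept) == n:
            break
    return sorted(kept)


def _pack_array(buf, arr):
    arr = np.ascontiguousarray(arr, dtype="<f8")
    buf.write(struct.pack("<Q", arr.size))
    buf.write(arr.tobytes())


def _unpack_array(buf):
    raw = buf.read(8)
    if len(raw) != 8:
        raise TableFormatError("truncated table file")
    (n,) = struct.unpack("<Q", raw)
    data = buf.read(8 * n)
    if len(data) != 8 * n:
        raise TableFormatError("truncated table file")
    return np.frombuffer(data, dtype="<f8").copy()


def write_table(table: StructureFactorTable, path, tsv_path=None) -> None:
    """Serialize to the documented binary layout plus a TSV mirror.

    Binary (little endian): magic "DISKSQTB", uint32 version, uint32 n_phi,
    uint32 n_q, uint32 spline degrees kx ky, then length-prefixed float64
    arrays phi_grid, q_grid, values (row-major), tx, ty, c, and a
    length-prefixed UTF-8 JSON provenance blob.  The TSV mirror holds one
    (phi, q, S) row per grid node.
    """
    path = str(path)
    tx, ty, c, kx, ky = table.tck
    buf = io.BytesIO()
    buf.write(_MAGIC)
    buf.write(struct.pack("<IIIII", _VERSION, len(table.phi_grid),
                          len(table.q_grid), kx, ky))
    for arr in (table.phi_grid, table.q_grid, table.values.ravel(), tx, ty, c):
        _pack_array(buf, arr)
    prov = json.dumps(table.provenance or []).encode()
    buf.write(struct.pack("<Q", len(prov)))
    buf.write(prov)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
    if tsv_path is None:
        tsv_path = path + ".tsv" if not path.endswith(".bin") else path[:-4] + ".tsv"
    with open(tsv_path, "w") as fh:
        fh.write("# structure factor table S(phi, q), QR scale (unit radius)\n")
        fh.write("phi\tq\tS\n")
        for i, p in enumerate(table.phi_grid):
            for j, x in enumerate(table.q_grid):
                fh.write(f"{p:.17g}\t{x:.17g}\t{table.values[i, j]:.17g}\n")


def read_table(path) -> StructureFactorTable:
    """Read the binary table format; raises TableFormatError on mismatch."""
    with open(str(path), "rb") as fh:
        data = fh.read()
    buf = io.BytesIO(data)
    if buf.read(8) != _MAGIC:
        raise TableFormatError("bad magic: not a disksq table file")
    head = buf.read(20)
    if len(head) != 20:
        raise TableFormatError("truncated table file")
    version, n_phi, n_q, kx, ky = struct.unpack("<IIIII", head)
    if version != _VERSION:
        raise TableFormatError(f"unsupported table version {version}")
    phi_grid = _unpack_array(buf)
    q_grid = _unpack_array(buf)
    values = _unpack_array(buf)
    tx = _unpack_array(buf)
    ty = _unpack_array(buf)
    c = _unpack_array(buf)
    if len(phi_grid) != n_phi or len(q_grid) != n_q or values.size != n_phi * n_q:
        raise TableFormatError("inconsistent table dimensions")
    raw = buf.read(8)
    if len(raw) != 8:
        raise TableFormatError("truncated table file")
    (np_len,) = struct.unpack("<Q", raw)
    prov_raw = buf.read(np_len)
    if len(prov_raw) != np_len:
        raise TableFormatError("truncated table file")
    provenance = json.loads(prov_raw.decode()) if np_len else []
    return StructureFactorTable(
        phi_grid=phi_grid, q_grid=q_grid,
        values=values.reshape(n_phi, n_q),
        tck=(tx, ty, c, int(kx), int(ky)),
        provenance=provenance,
    )
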