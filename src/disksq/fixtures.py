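"""Deterministic small inputs for tests and examples.

Kinds:
  lattice        perfect hexagonal lattice (first neighbor distance = a)
  uniform_points uniform random points, no hard core (g = 1 oracle)
  dilute         short equilibrated hard-disk run at low area fraction
  two_disk       two disks at a prescribed distance (single-bin histogram)
  saxs_profile   synthetic noisy intensity from the cylinder product model
"""

from __future__ import annotations

import math

import numpy as np

from . import analytic, packing

__all__ = ["make_fixture"]


def _lattice(params, rng):
    phi0 = params.get("phi0", 0.5)
    l = params.get("l", 40.0)
    return packing.hexagonal_init(packing.PackingSpec(phi0=phi0, l=l))


def _uniform_points(params, rng):
    l = params.get("l", 100.0)
    n = params.get("n", int(params.get("density", 0.05) * l * l))
    positions = rng.uniform(0.0, l, size=(n, 2))
    # point particles: a = 0-spacing placeholder, phi0 formally n*pi/l^2
    return packing.DiskConfiguration(
        l=l, positions=positions, a=float("nan"), n_x=0, n_y=0,
        phi0=n * math.pi / l**2,
    )


def _dilute(params, rng):
    phi0 = params.get("phi0", 0.05)
    l = params.get("l", 60.0)
    seed = int(rng.integers(2**31))
    spec = packing.PackingSpec(phi0=phi0, l=l, seed=seed)
    samples, _ = packing.run_simulation(spec, n_sweeps=150, sample_interval=50,
                                        burn_in=100)
    return samples[-1]


def _two_disk(params, rng):
    l = params.get("l", 20.0)
    distance = params.get("distance", 5.03)
    c = l / 2.0
    positions = np.array([[c - distance / 2.0, c], [c + distance / 2.0, c]])
    return packing.DiskConfiguration(
        l=l, positions=positions, a=distance, n_x=2, n_y=1,
        phi0=2 * math.pi / l**2,
    )


def _saxs_profile(params, rng):
    model = analytic.CylinderModel(
        radius=params.get("radius", 13.0), phi=params.get("phi", 0.4),
        scale=params.get("scale", 1.0), background=params.get("background", 0.0),
    )
    q = np.asarray(params.get("q_grid", np.linspace(0.005, 0.6, 200)))
    clean = analytic.saxs_intensity(q, model)
    noise = params.get("noise", 0.02)
    return q, clean * (1.0 + noise * rng.standard_normal(len(q)))


_KINDS = {
    "lattice": _lattice,
    "uniform_points": _uniform_points,
    "dilute": _dilute,
    "two_disk": _two_disk,
    "saxs_profile": _saxs_profile,
}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a deterministic test input of the given kind."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(_KINDS)}")
    return _KINDS[kind](params or {}, np.random.default_rng(seed))
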