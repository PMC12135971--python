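"""Shared fixtures: small deterministic configurations and the scaled-down
simulation runs reused across the acceptance checks.

All seeds are fixed constants so every run of the suite sees identical
trajectories.  The heavy session fixtures are lazy: they only run when a
test that needs them is collected.
"""

import numpy as np
import pytest

from disksq import packing, pipeline
from disksq.pipeline import (BAND_RUN, DILUTE_RUN, PEAK_RUN, ROSENFELD_RUN,
                             TRUNCATION_RUN)


def brute_force_min_distance(config):
    """Minimum pairwise minimum-image distance, O(N^2)."""
    p = config.positions
    d = np.abs(p[:, None, :] - p[None, :, :])
    d = np.minimum(d, config.l - d)
    dist = np.hypot(d[..., 0], d[..., 1])
    dist[np.diag_indices(len(p))] = np.inf
    return dist.min()


def brute_force_collision(config, disk_id, proposed):
    """Reference collision check against every other disk."""
    p = np.delete(config.positions, disk_id, axis=0)
    d = np.abs(p - proposed)
    d = np.minimum(d, config.l - d)
    return bool(np.any(np.hypot(d[:, 0], d[:, 1]) < 2.0))


@pytest.fixture(scope="session")
def melted_config():
    """A small equilibrated hard-disk configuration (l=40, phi=0.3)."""
    spec = packing.PackingSpec(phi0=0.3, l=40.0, seed=9)
    samples, _ = packing.run_simulation(spec, n_sweeps=300, sample_interval=100,
                                        burn_in=100)
    return samples[-1]


@pytest.fixture(scope="session")
def dilute_run():
    """phi = 0.05 run with per-sample PDFs kept (dilute-limit oracles)."""
    pdf, info = pipeline.simulate_pdf(0.05, seed=1005, keep_samples=True,
                                      **DILUTE_RUN)
    return pdf, info


@pytest.fixture(scope="session")
def run071_pdf():
    """phi = 0.71 averaged PDF for the peak-position acceptance surface."""
    pdf, info = pipeline.simulate_pdf(0.71, seed=1071, **PEAK_RUN)
    return pdf, info


@pytest.fixture(scope="session")
def trunc06_pdf():
    """phi = 0.6 averaged PDF in an l = 400 box (r_max up to 200)."""
    pdf, info = pipeline.simulate_pdf(0.6, seed=1006, **TRUNCATION_RUN)
    return pdf, info


@pytest.fixture(scope="session")
def rosenfeld_band_curves():
    """Smoothed S(Q) curves at phi0 in {0.10, 0.15, 0.20, 0.25}."""
    curves = {}
    for i, phi0 in enumerate((0.10, 0.15, 0.20, 0.25)):
        pdf, _ = pipeline.simulate_pdf(phi0, seed=1010 + i, **ROSENFELD_RUN)
        curves[phi0] = pipeline.pdf_to_curve(pdf)
    return curves


@pytest.fixture(scope="session")
def band_table():
    """Spline table over phi0 in {0.30 .. 0.50} (wood-comparison band)."""
    curves = []
    for i, phi0 in enumerate((0.30, 0.35, 0.40, 0.45, 0.50)):
        pdf, _ = pipeline.simulate_pdf(phi0, seed=1030 + i, **BAND_RUN)
        curves.append(pipeline.pdf_to_curve(pdf))
    from disksq.table import fit_bivariate_spline
    return fit_bivariate_spline(curves, smoothing=0.1)
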