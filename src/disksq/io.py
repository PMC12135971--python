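"""Plain-text IO: snapshots, curve TSVs, key = value config files."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .packing import DiskConfiguration

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_curve",
    "read_curve",
    "read_config_file",
]


def write_snapshot(config: DiskConfiguration, path) -> None:
    """One "x y" pair per line at 17 significant digits, with '#' headers
    recording l, phi0, phi_actual, seed and sweep index."""
    with open(str(path), "w") as fh:
        fh.write(f"# l = {config.l:.17g}\n")
        fh.write(f"# phi0 = {config.phi0:.17g}\n")
        fh.write(f"# phi_actual = {config.phi_actual:.17g}\n")
        fh.write(f"# a = {config.a:.17g}\n")
        fh.write(f"# n_x = {config.n_x}\n# n_y = {config.n_y}\n")
        fh.write(f"# seed = {config.seed}\n# sweep = {config.sweep}\n")
        for x, y in config.positions:
            fh.write(f"{x:.17g} {y:.17g}\n")


def read_snapshot(path) -> DiskConfiguration:
    meta = {}
    rows = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            else:
                rows.append([float(t) for t in line.split()])
    positions = np.array(rows, dtype=np.float64).reshape(-1, 2)
    return DiskConfiguration(
        l=float(meta["l"]), positions=positions,
        a=float(meta.get("a", "nan")),
        n_x=int(meta.get("n_x", 0)), n_y=int(meta.get("n_y", 0)),
        phi0=float(meta.get("phi0", len(positions) * math.pi / float(meta["l"])**2)),
        seed=int(meta.get("seed", 0)), sweep=int(meta.get("sweep", 0)),
    )


def write_curve(path, x, y, columns=("q", "S"), meta: dict | None = None) -> None:
    """Two-column TSV with '#' metadata headers."""
    with open(str(path), "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write(f"# {columns[0]}\t{columns[1]}\n")
        for xi, yi in zip(np.asarray(x), np.asarray(y)):
            fh.write(f"{xi:.17g}\t{yi:.17g}\n")


def read_curve(path):
    """Returns (x, y, meta) from a curve TSV."""
    meta = {}
    xs, ys = [], []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, eq, value = line[1:].partition("=")
                if eq:
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    return np.array(xs), np.array(ys), meta


def read_config_file(path) -> dict:
    """Parse a plain-text "key = value" configuration file.

    Blank lines and '#' comments are ignored; values stay strings and are
    coerced by the consuming option parser.
    """
    out = {}
    for line in Path(str(path)).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, eq, value = line.partition("=")
        if not eq:
            raise ValueError(f"malformed config line: {line!r}")
        out[key.strip()] = value.strip()
    return out
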