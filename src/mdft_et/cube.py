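"""Gaussian cube output for spatial scalar fields (coordinates in Bohr)."""

from __future__ import annotations

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .grids import SpatialGrid

__all__ = ["write_cube"]


def write_cube(field3d: np.ndarray, grid: SpatialGrid, path, comment: str = "") -> None:
    nx, ny, nz = grid.shape
    d = grid.spacing * BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("volumetric field on a periodic grid\n")
        fh.write(f"{0:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nx:5d} {d[0]:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {d[1]:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {d[2]:12.6f}\n")
        flat = field3d.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                chunk = row[start : start + 6]
                fh.write(" ".join(f"{v:13.5E}" for v in chunk) + "\n")
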