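"""Post-processing of equilibrium solvent densities.

Solvent charge density, spherical averages around a solute, planar
slices and the depletion-integral partial molar volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DensityField, SpatialGrid, number_density
from .systems import SolventModel

__all__ = [
    "RadialProfile",
    "solvent_charge_density",
    "spherical_average",
    "partial_molar_volume",
    "planar_slice",
    "write_slice_tsv",
]


@dataclass
class RadialProfile:
    r: np.ndarray  # bin centers, Å
    values: np.ndarray  # NaN where a shell holds no voxel
    bin_width: float
    center: np.ndarray

    def to_tsv(self, path, value_name: str = "value") -> None:
        with open(path, "w") as fh:
            fh.write(f"# center = {self.center.tolist()} (Å), bin width {self.bin_width} Å\n")
            fh.write(f"r_angstrom\t{value_name}\n")
            for r, v in zip(self.r, self.values):
                fh.write(f"{r:.10g}\t{v:.10g}\n")


def solvent_charge_density(
    fieldobj: DensityField, solvent: SolventModel, spread_width: float = 0.0
) -> np.ndarray:
    """Solvent charge density ρ_c(r) in e·Å⁻³.

    Every molecule with centre of mass at r′ and orientation Ω deposits
    its site charges q_i at r′ + r_iΩ.  The sum over molecules is a
    convolution, done in reciprocal space with the per-orientation
    molecular form factor Σ_i q_i exp(−i k·r_iΩ).  ``spread_width`` > 0
    additionally smears each site charge with a Gaussian of that width
    (use the electrostatic solver's width for internal consistency);
    0 keeps exact point placement, band-limited by the grid.
    """
    q = solvent.site_charges()
    if abs(q.sum()) > 1e-10:
        raise ValueError("solvent molecules must be neutral")
    grid, quad = fieldobj.grid, fieldobj.quad
    body = solvent.site_positions()
    rots = quad.rotation_matrices()
    k = grid.kvectors()
    k2 = np.einsum("xyzi,xyzi->xyz", k, k)
    smear = np.exp(-0.5 * k2 * spread_width**2) if spread_width > 0 else 1.0

    rho_c_k = np.zeros(grid.shape, complex)
    for m in range(quad.n_orientations):
        rho_k = np.fft.fftn(fieldobj.values[..., m])
        form = np.zeros(grid.shape, complex)
        for qi, b in zip(q, body):
            if qi == 0.0:
                continue
            r_i = rots[m] @ b
            form += qi * np.exp(-1j * np.einsum("xyzi,i->xyz", k, r_i))
        rho_c_k += quad.weights[m] * rho_k * form
    return np.fft.ifftn(rho_c_k * smear).real


def spherical_average(
    field3d: np.ndarray,
    grid: SpatialGrid,
    center,
    bin_width: float,
    r_max: float | None = None,
) -> RadialProfile:
    """Volume-weighted shell average of a spatial field around ``center``.

    Distances use the minimum image; shells with no voxels are returned
    as NaN rather than zero.
    """
    center = np.asarray(center, float)
    if np.any(center < 0) or np.any(center >= np.asarray(grid.box_lengths)):
        raise ValueError("center must lie inside the box")
    dr = grid.minimum_image(grid.coordinates() - center)
    dist = np.sqrt(np.einsum("xyzi,xyzi->xyz", dr, dr)).ravel()
    rmax = r_max if r_max is not None else 0.5 * min(grid.box_lengths)
    nbins = int(np.ceil(rmax / bin_width))
    idx = np.minimum((dist / bin_width).astype(int), nbins)  # overflow bin at nbins
    counts = np.bincount(idx, minlength=nbins + 1)[:nbins]
    sums = np.bincount(idx, weights=field3d.ravel(), minlength=nbins + 1)[:nbins]
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    r = (np.arange(nbins) + 0.5) * bin_width
    return RadialProfile(r, vals, bin_width, center)


def partial_molar_volume(fieldobj: DensityField) -> float:
    """Depletion-volume estimator ΔV = −(1/n_H) ∫ Δn(r) dr, in Å³.

    No compressibility term: this is the bare solvent-depletion
    integral, which equals the excluded volume for a hard core.
    """
    n = number_density(fieldobj)
    dn = n - fieldobj.n_bulk
    return float(-dn.sum() * fieldobj.grid.voxel_volume / fieldobj.n_bulk)


def planar_slice(field3d: np.ndarray, grid: SpatialGrid, axis: int, coordinate: float) -> np.ndarray:
    """Nearest-plane extraction, no interpolation."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if not 0.0 <= coordinate < grid.box_lengths[axis]:
        raise ValueError("coordinate outside the box")
    i = int(np.round(coordinate / grid.spacing[axis])) % grid.shape[axis]
    return np.take(field3d, i, axis=axis)


def write_slice_tsv(slice2d: np.ndarray, path, comment: str = "") -> None:
    """Save a 2D slice as a TSV matrix (one row per line)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in np.atleast_2d(slice2d):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
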