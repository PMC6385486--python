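"""Discrete fields over positions and orientations.

The solvent density ρ(r, Ω) lives on the product of a periodic spatial
grid and an orientation quadrature over the three ZYZ Euler angles
(θ, φ, ψ).  All integrals are quadrature sums: voxel volume times
orientational weight.  The orientational measure is 8π²/σ_sym, with
σ_sym the molecular symmetry order (2 for C2v solvents such as water).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SpatialGrid",
    "OrientationQuadrature",
    "DensityField",
    "PotentialField",
    "build_spatial_grid",
    "build_orientation_quadrature",
    "integrate_field",
    "number_density",
]


@dataclass(frozen=True)
class SpatialGrid:
    """Periodic rectangular grid with nodes at i·Δ (corner convention)."""

    box_lengths: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.box_lengths):
            raise ValueError("box lengths must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("need at least 2 grid points per axis")

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.box_lengths) / np.asarray(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        return float(np.prod(self.box_lengths))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        return np.arange(self.shape[axis]) * self.spacing[axis]

    def coordinates(self) -> np.ndarray:
        """Voxel positions, shape (nx, ny, nz, 3)."""
        ax = [self.axis_coordinates(i) for i in range(3)]
        out = np.empty(self.shape + (3,))
        out[..., 0], out[..., 1], out[..., 2] = np.meshgrid(*ax, indexing="ij")
        return out

    def kvectors(self) -> np.ndarray:
        """Reciprocal lattice wavevectors (rad/Å), shape (nx, ny, nz, 3)."""
        ks = [
            2.0 * np.pi * np.fft.fftfreq(n, d=d)
            for n, d in zip(self.shape, self.spacing)
        ]
        out = np.empty(self.shape + (3,))
        out[..., 0], out[..., 1], out[..., 2] = np.meshgrid(*ks, indexing="ij")
        return out

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Wrap displacement vectors into the central periodic image."""
        L = np.asarray(self.box_lengths)
        return dr - L * np.round(dr / L)

    def same_as(self, other: "SpatialGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.box_lengths, other.box_lengths, rtol=0, atol=0
        )


def build_spatial_grid(box_lengths, points_per_axis) -> SpatialGrid:
    return SpatialGrid(
        tuple(float(L) for L in box_lengths),
        tuple(int(n) for n in points_per_axis),
    )


@dataclass(frozen=True)
class OrientationQuadrature:
    """Product quadrature over ZYZ Euler angles.

    Gauss–Legendre nodes in cosθ, uniform (trapezoidal, periodic) nodes
    in φ ∈ [0, 2π) and ψ ∈ [0, 2π/σ_sym).  Weights sum to 8π²/σ_sym and
    the rule integrates Wigner functions exactly up to the declared
    order (min(n_theta-1, n_phi-1, ...) in the usual product sense).
    """

    nodes: np.ndarray  # (M, 3) columns θ, φ, ψ
    weights: np.ndarray  # (M,)
    symmetry_order: int

    @property
    def n_orientations(self) -> int:
        return len(self.weights)

    @property
    def measure(self) -> float:
        return 8.0 * np.pi**2 / self.symmetry_order

    def rotation_matrices(self) -> np.ndarray:
        """Body→lab rotation matrices R(θ, φ, ψ), shape (M, 3, 3)."""
        theta, phi, psi = self.nodes.T
        angles = np.column_stack([phi, theta, psi])
        return Rotation.from_euler("ZYZ", angles).as_matrix()

    def molecular_axes(self) -> np.ndarray:
        """Lab-frame image of the body z-axis for every node, (M, 3)."""
        theta, phi, _ = self.nodes.T
        st = np.sin(theta)
        return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def build_orientation_quadrature(
    n_theta: int, n_phi: int, n_psi: int, symmetry_order: int = 1
) -> OrientationQuadrature:
    if symmetry_order < 1:
        raise ValueError("symmetry_order must be >= 1")
    if min(n_theta, n_phi, n_psi) < 1:
        raise ValueError("need at least one node per Euler angle")
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    wphi = 2.0 * np.pi / n_phi
    psi_span = 2.0 * np.pi / symmetry_order
    psi = psi_span * np.arange(n_psi) / n_psi
    wpsi = psi_span / n_psi

    T, P, S = np.meshgrid(theta, phi, psi, indexing="ij")
    W = np.meshgrid(wx, np.full(n_phi, wphi), np.full(n_psi, wpsi), indexing="ij")
    nodes = np.column_stack([T.ravel(), P.ravel(), S.ravel()])
    weights = (W[0] * W[1] * W[2]).ravel()
    return OrientationQuadrature(nodes, weights, symmetry_order)


def _check_shapes(values: np.ndarray, grid: SpatialGrid, quad: OrientationQuadrature):
    expected = grid.shape + (quad.n_orientations,)
    if values.shape != expected:
        raise ValueError(f"field shape {values.shape} != expected {expected}")


@dataclass
class DensityField:
    """Solvent density ρ(r, Ω) in Å⁻³ per unit orientational measure.

    ``validate=False`` admits signed fields: the linear-response
    (quadratic ideal) model produces densities that may undershoot zero,
    and density *deviations* Δρ are naturally signed.
    """

    values: np.ndarray
    grid: SpatialGrid
    quad: OrientationQuadrature
    rho_bulk: float
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        _check_shapes(self.values, self.grid, self.quad)
        if self.validate and np.any(self.values < 0):
            raise ValueError("density field must be non-negative")

    @classmethod
    def bulk(cls, grid, quad, n_bulk: float) -> "DensityField":
        rho = n_bulk / quad.measure
        vals = np.full(grid.shape + (quad.n_orientations,), rho)
        return cls(vals, grid, quad, rho)

    @property
    def n_bulk(self) -> float:
        return self.rho_bulk * self.quad.measure

    def delta(self) -> np.ndarray:
        return self.values - self.rho_bulk

    def copy_with(self, values: np.ndarray, validate: bool = True) -> "DensityField":
        return DensityField(values, self.grid, self.quad, self.rho_bulk, validate)


@dataclass
class PotentialField:
    """External potential V(r, Ω) in kJ/mol, capped at ``cap_value``."""

    values: np.ndarray
    grid: SpatialGrid
    quad: OrientationQuadrature
    cap_value: float

    def __post_init__(self) -> None:
        _check_shapes(self.values, self.grid, self.quad)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential contains non-finite values")
        if np.any(self.values > self.cap_value + 1e-12):
            raise ValueError("potential exceeds its declared cap")


def integrate_field(
    values: np.ndarray, grid: SpatialGrid, quad: OrientationQuadrature
) -> float:
    """∫∫ f(r, Ω) dr dΩ as Σ_voxels Σ_nodes f · ΔV · w."""
    _check_shapes(values, grid, quad)
    return float(grid.voxel_volume * np.einsum("xyzo,o->", values, quad.weights))


def number_density(fieldlike) -> np.ndarray:
    """n(r) = ∫ ρ(r, Ω) dΩ, shape (nx, ny, nz)."""
    return np.einsum("xyzo,o->xyz", fieldlike.values, fieldlike.quad.weights)
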