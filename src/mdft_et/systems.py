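"""Solvent and solute models, and construction of external potentials.

A solvent molecule is a rigid set of interaction sites given in a body
frame; a solute state is a rigid set of sites in the box frame.  The
external potential felt by a solvent molecule at (r, Ω) is the sum over
solvent-site/solute-site pairs of Lennard-Jones and Coulomb terms,
evaluated at the rotated site positions r_iΩ = r + R(Ω)·b_i.

Electron-transfer states 0 and 1 share their Lennard-Jones sites and
differ only in charges; intermediate states are the affine family
V_η = V_0 + η(V_1 − V_0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .constants import COULOMB, DEFAULT_CAP_KT, KB
from .grids import OrientationQuadrature, PotentialField, SpatialGrid

__all__ = [
    "SolventSite",
    "SolventModel",
    "SoluteState",
    "EtaSchedule",
    "spce_water",
    "toy_dipolar_solvent",
    "build_external_potential",
    "interpolate_potentials",
    "hard_core_potential",
    "build_fcc100_wall",
]


@dataclass(frozen=True)
class SolventSite:
    name: str
    position: tuple[float, float, float]  # body frame, Å
    charge: float  # e
    sigma: float  # Å
    epsilon: float  # kJ/mol


@dataclass(frozen=True)
class SolventModel:
    """Rigid solvent: sites in a body frame, bulk density, temperature."""

    sites: tuple[SolventSite, ...]
    n_bulk: float  # Å⁻³
    temperature: float  # K
    symmetry_order: int = 1
    name: str = "solvent"

    def __post_init__(self) -> None:
        if self.n_bulk <= 0 or self.temperature <= 0:
            raise ValueError("bulk density and temperature must be positive")
        q = sum(s.charge for s in self.sites)
        if abs(q) > 1e-10:
            raise ValueError(f"solvent molecule must be neutral, net charge {q}")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def rho_bulk(self, quad: OrientationQuadrature) -> float:
        return self.n_bulk / quad.measure

    def site_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    def site_charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])


def spce_water() -> SolventModel:
    """SPC/E water at ambient conditions (σ_sym = 2 for C2v)."""
    r_oh = 1.0
    half = np.deg2rad(109.47 / 2.0)
    hx, hz = r_oh * np.sin(half), r_oh * np.cos(half)
    return SolventModel(
        sites=(
            SolventSite("O", (0.0, 0.0, 0.0), -0.8476, 3.166, 0.650),
            SolventSite("H1", (hx, 0.0, hz), 0.4238, 0.0, 0.0),
            SolventSite("H2", (-hx, 0.0, hz), 0.4238, 0.0, 0.0),
        ),
        n_bulk=0.0333,
        temperature=298.15,
        symmetry_order=2,
        name="SPC/E",
    )


def toy_dipolar_solvent() -> SolventModel:
    """Small neutral 3-site solvent with a dipole along the body z-axis.

    Deliberately light (short bonds, modest charges) so that coarse
    orientation quadratures integrate its potentials accurately; used
    with the analytic dipolar kernel for desk-scale studies.
    """
    return SolventModel(
        sites=(
            SolventSite("M", (0.0, 0.0, -0.3), -0.5, 2.9, 0.50),
            SolventSite("P1", (0.0, 0.0, 0.3), 0.25, 0.0, 0.0),
            SolventSite("P2", (0.0, 0.0, 0.5), 0.25, 0.0, 0.0),
        ),
        n_bulk=0.0333,
        temperature=298.15,
        symmetry_order=1,
        name="toy-dipolar",
    )


@dataclass(frozen=True)
class SoluteState:
    """Rigid solute: site arrays in the box frame (Å, e, Å, kJ/mol)."""

    positions: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,)
    sigmas: np.ndarray  # (n,)
    epsilons: np.ndarray  # (n,)
    label: str = "state"
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.atleast_2d(np.asarray(self.positions, float)))
        for attr in ("charges", "sigmas", "epsilons"):
            object.__setattr__(self, attr, np.atleast_1d(np.asarray(getattr(self, attr), float)))
        n = len(self.positions)
        if not (len(self.charges) == len(self.sigmas) == len(self.epsilons) == n):
            raise ValueError("site arrays must have identical lengths")
        if not self.names:
            object.__setattr__(self, "names", tuple(f"X{i}" for i in range(n)))
        if np.any((self.sigmas == 0) & (self.epsilons != 0)):
            raise ValueError("zero sigma with nonzero epsilon is ill-defined")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def with_charges(self, charges, label: str | None = None) -> "SoluteState":
        return replace(self, charges=np.asarray(charges, float),
                       label=label or self.label)

    def translated(self, shift) -> "SoluteState":
        return replace(self, positions=self.positions + np.asarray(shift, float))

    def merged_with(self, other: "SoluteState", label: str | None = None) -> "SoluteState":
        """Concatenate site lists (e.g. wall + redox site).

        Solute sites only ever act on the solvent; merging never creates
        solute–solute interaction terms.
        """
        return SoluteState(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.charges, other.charges]),
            np.concatenate([self.sigmas, other.sigmas]),
            np.concatenate([self.epsilons, other.epsilons]),
            label=label or f"{self.label}+{other.label}",
            names=self.names + other.names,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.positions)}\n")
            fh.write(f"# label={self.label} net_charge={self.net_charge:.6f}\n")
            for name, p, q, s, e in zip(
                self.names, self.positions, self.charges, self.sigmas, self.epsilons
            ):
                fh.write(
                    f"{name} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                    f"{q:.10g} {s:.10g} {e:.10g}\n"
                )

    @classmethod
    def from_file(cls, path) -> "SoluteState":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        n = int(lines[0])
        label = "state"
        body = lines[1:]
        if body and body[0].startswith("#"):
            for tok in body[0][1:].split():
                if tok.startswith("label="):
                    label = tok[6:]
            body = body[1:]
        names, pos, q, s, e = [], [], [], [], []
        for ln in body[:n]:
            parts = ln.split()
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            q.append(float(parts[4]))
            s.append(float(parts[5]))
            e.append(float(parts[6]))
        return cls(np.array(pos), np.array(q), np.array(s), np.array(e),
                   label=label, names=tuple(names))


@dataclass(frozen=True)
class EtaSchedule:
    """Ordered coupling values η ∈ [0, 1] with optional reparametrization.

    The effective couplings driving the potentials are s(η); s must be
    strictly increasing with s(0)=0 and s(1)=1 so the endpoint states
    are preserved (any such s yields the same free-energy curve).
    """

    etas: tuple[float, ...]
    reparametrization: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.etas, float)
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if np.any(np.diff(e) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.reparametrization is not None:
            s = self.reparametrization
            if abs(s(0.0)) > 1e-12 or abs(s(1.0) - 1.0) > 1e-12:
                raise ValueError("reparametrization must fix the endpoints")

    @classmethod
    def uniform(cls, n: int = 11) -> "EtaSchedule":
        return cls(tuple(np.linspace(0.0, 1.0, n)))

    @property
    def couplings(self) -> np.ndarray:
        e = np.asarray(self.etas, float)
        if self.reparametrization is None:
            return e
        return np.array([self.reparametrization(x) for x in e])


# ---------------------------------------------------------------------------
# External potential construction
# ---------------------------------------------------------------------------


def _lj_on_points(points, grid, solute, sigma_i, eps_i, cutoff):
    """Σ_j 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] at the given points, minimum image."""
    out = np.zeros(points.shape[:-1])
    for pj, sj, ej in zip(solute.positions, solute.sigmas, solute.epsilons):
        if ej == 0.0 or eps_i == 0.0:
            continue
        sij = 0.5 * (sigma_i + sj)
        eij = np.sqrt(eps_i * ej)
        dr = grid.minimum_image(points - pj)
        r2 = np.einsum("...i,...i->...", dr, dr)
        np.maximum(r2, 1e-12, out=r2)
        mask = r2 < cutoff * cutoff
        s6 = (sij * sij / r2[mask]) ** 3
        out[mask] += 4.0 * eij * (s6 * s6 - s6)
    return out


def _spread_charges_k(grid: SpatialGrid, positions, charges, width):
    """Fourier transform of Gaussian-spread point charges (continuum units)."""
    k = grid.kvectors()
    k2 = np.einsum("xyzi,xyzi->xyz", k, k)
    rho_k = np.zeros(grid.shape, complex)
    for p, q in zip(positions, charges):
        rho_k += q * np.exp(-1j * np.einsum("xyzi,i->xyz", k, p))
    rho_k *= np.exp(-0.5 * k2 * width * width)
    return rho_k, k2


def _periodic_potential_grid(grid, positions, charges, width):
    """Solve the periodic Poisson equation for spread charges.

    Tinfoil convention: the k = 0 mode is zeroed, i.e. a neutralizing
    background absorbs any net solute charge.
    """
    rho_k, k2 = _spread_charges_k(grid, positions, charges, width)
    phi_k = np.zeros_like(rho_k)
    nz = k2 > 0
    phi_k[nz] = 4.0 * np.pi * COULOMB * rho_k[nz] / k2[nz]
    return np.fft.ifftn(phi_k).real / grid.voxel_volume


def _interp_periodic(field3d, grid, points):
    frac = points / grid.spacing  # grid-index coordinates
    coords = np.moveaxis(frac, -1, 0).reshape(3, -1)
    out = map_coordinates(field3d, coords, order=1, mode="grid-wrap")
    return out.reshape(points.shape[:-1])


def build_external_potential(
    solute: SoluteState,
    solvent: SolventModel,
    grid: SpatialGrid,
    quad: OrientationQuadrature,
    electrostatics: str = "periodic",
    lj_cutoff: float | None = None,
    cap_kt: float = DEFAULT_CAP_KT,
    gaussian_width: float | None = None,
) -> PotentialField:
    """Map a rigid solute onto V(r, Ω) felt by one solvent molecule.

    Lennard-Jones terms use Lorentz–Berthelot mixing, minimum image and
    a real-space cutoff (default min(box)/2, no tail correction).
    Electrostatics is either a periodic grid Poisson solve with
    Gaussian-spread charges read back by trilinear interpolation
    (``periodic``, the production mode) or an open-boundary direct sum
    (``direct``, exact for validation).  The result is capped at
    ``cap_kt``·k_B·T.
    """
    box = np.asarray(grid.box_lengths)
    if np.any(solute.positions < 0) or np.any(solute.positions >= box):
        raise ValueError("solute sites must lie inside the box [0, L)")
    if electrostatics not in ("periodic", "direct", "none"):
        raise ValueError(f"unknown electrostatics mode {electrostatics!r}")

    cutoff = lj_cutoff if lj_cutoff is not None else 0.5 * min(grid.box_lengths)
    width = gaussian_width if gaussian_width is not None else float(np.max(grid.spacing))
    coords = grid.coordinates()
    rots = quad.rotation_matrices()
    V = np.zeros(grid.shape + (quad.n_orientations,))

    any_charge = np.any(solute.charges != 0.0)
    phi = None
    if electrostatics == "periodic" and any_charge:
        phi = _periodic_potential_grid(grid, solute.positions, solute.charges, width)

    for site in solvent.sites:
        b = np.asarray(site.position)
        for m in range(quad.n_orientations):
            pts = coords + rots[m] @ b
            if site.epsilon != 0.0:
                V[..., m] += _lj_on_points(pts, grid, solute, site.sigma, site.epsilon, cutoff)
            if site.charge != 0.0 and any_charge:
                if electrostatics == "periodic":
                    V[..., m] += site.charge * _interp_periodic(phi, grid, pts)
                elif electrostatics == "direct":
                    for pj, qj in zip(solute.positions, solute.charges):
                        if qj == 0.0:
                            continue
                        d = np.linalg.norm(pts - pj, axis=-1)
                        np.maximum(d, 1e-10, out=d)
                        V[..., m] += COULOMB * site.charge * qj / d

    cap = cap_kt * solvent.kT
    np.minimum(V, cap, out=V)
    return PotentialField(V, grid, quad, cap)


def interpolate_potentials(V0: PotentialField, V1: PotentialField, eta: float) -> PotentialField:
    """V_η = V_0 + η(V_1 − V_0), pointwise; endpoints are returned exactly."""
    if not V0.grid.same_as(V1.grid) or V0.quad.n_orientations != V1.quad.n_orientations:
        raise ValueError("potentials live on different grids")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if eta == 0.0:
        return PotentialField(V0.values, V0.grid, V0.quad, V0.cap_value)
    if eta == 1.0:
        return PotentialField(V1.values, V1.grid, V1.quad, V1.cap_value)
    vals = V0.values + eta * (V1.values - V0.values)
    return PotentialField(vals, V0.grid, V0.quad, max(V0.cap_value, V1.cap_value))


def hard_core_potential(
    grid: SpatialGrid,
    quad: OrientationQuadrature,
    center,
    radius: float,
    kT: float,
    cap_kt: float = DEFAULT_CAP_KT,
    subsamples: int = 4,
) -> PotentialField:
    """Capped hard-sphere exclusion, voxel-averaged to kill grid aliasing.

    A sharp indicator sampled at voxel nodes misplaces the spherical
    boundary by up to half a voxel.  Instead each voxel stores the
    Boltzmann-consistent value V = −kT ln(1 − χ(1 − e^{−βcap})) where χ
    is the in-sphere fraction of the voxel (``subsamples``³ points), so
    the voxel-averaged Boltzmann factor of the true hard core is exact
    up to the sub-voxel quadrature.
    """
    center = np.asarray(center, float)
    sub = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    offsets = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"), -1).reshape(-1, 3)
    offsets *= grid.spacing
    coords = grid.coordinates()
    chi = np.zeros(grid.shape)
    for off in offsets:
        dr = grid.minimum_image(coords + off - center)
        chi += (np.einsum("...i,...i->...", dr, dr) < radius * radius)
    chi /= len(offsets)
    cap = cap_kt * kT
    boltz_in = np.exp(-cap / kT)
    with np.errstate(divide="ignore"):
        V = -kT * np.log1p(-chi * (1.0 - boltz_in))
    V = np.minimum(V, cap)  # fully buried voxels saturate at the cap
    vals = np.repeat(V[..., None], quad.n_orientations, axis=-1)
    return PotentialField(vals, grid, quad, cap)


def build_fcc100_wall(
    lattice_spacing: float,
    n_atoms_per_side: int,
    lj_sigma: float,
    lj_epsilon: float,
    z: float = 0.0,
    origin: Sequence[float] = (0.0, 0.0),
    box_lengths: Sequence[float] | None = None,
    label: str = "wall",
) -> SoluteState:
    """Single square layer of uncharged LJ atoms: a (100) fcc surface.

    With spacing 2 Å and 20 atoms per side this is the 400-atom,
    40 × 40 Å² wall; neighbouring atoms sit ``lattice_spacing`` apart.
    """
    span = n_atoms_per_side * lattice_spacing
    if box_lengths is not None:
        if span > box_lengths[0] + 1e-9 or span > box_lengths[1] + 1e-9:
            raise ValueError("wall exceeds the box cross-section")
    i = np.arange(n_atoms_per_side) * lattice_spacing
    X, Y = np.meshgrid(i + origin[0], i + origin[1], indexing="ij")
    n = n_atoms_per_side**2
    pos = np.column_stack([X.ravel(), Y.ravel(), np.full(n, z)])
    return SoluteState(
        pos,
        np.zeros(n),
        np.full(n, lj_sigma),
        np.full(n, lj_epsilon),
        label=label,
    )
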