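"""Bulk direct correlation function kernels and the convolution γ = c ★ Δρ.

The excess (solvent–solvent) functional needs the angular convolution

    γ(r, Ω) = ∫∫ c(|r − r′|, Ω, Ω′) Δρ(r′, Ω′) dr′ dΩ′ .

Kernels are held as rotational-invariant projections ĉ^{mnl}_{μν}(k).
The convolution is evaluated in reciprocal space where it becomes,
channel by channel, a product of projections with the generalized
moments of Δρ.  Version 1 convolves projections up to m = n = 1 with
μ = ν = 0 (the density/dipole sector): the isotropic channel ĉ_S acting
on the number density and the longitudinal/transverse dipole channels
ĉ_L, ĉ_T acting on the polarization density.  The table reader accepts
and preserves arbitrary higher-order blocks; convolution raises if they
are non-zero.

Internally the dipole sector is stored in the invariant basis
(Φ^{110} = u₁·u₂ and Φ^{112} = 3(u₁·k̂)(u₂·k̂) − u₁·u₂):
c_Δ = (c_L + 2c_T)/3 and c_D = (c_L − c_T)/3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .grids import OrientationQuadrature, SpatialGrid

__all__ = [
    "CorrelationKernel",
    "make_builtin_kernel",
    "load_kernel_table",
    "write_kernel_table",
    "convolve_kernel",
    "kernel_bulk_pressure",
]

#: blocks the convolution engine knows how to apply
_SUPPORTED_BLOCKS = {(0, 0, 0, 0, 0), (1, 1, 0, 0, 0), (1, 1, 2, 0, 0)}


@dataclass
class CorrelationKernel:
    """Direct correlation function in rotational-invariant projections.

    ``kind`` is one of ``zero``, ``dipolar-toy`` or
    ``tabulated-invariants``.  Analytic kinds store Gaussian channel
    amplitudes/widths; tabulated kinds store a strictly increasing
    k-grid and complex projection arrays per (m, n, l, μ, ν) block.
    """

    kind: str
    k_grid: np.ndarray | None = None
    blocks: dict[tuple[int, int, int, int, int], np.ndarray] = field(default_factory=dict)
    toy_params: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_grid is not None:
            k = np.asarray(self.k_grid, float)
            if k[0] < 0 or np.any(np.diff(k) <= 0):
                raise ValueError("k grid must be strictly increasing from >= 0")
            for key, v in self.blocks.items():
                if len(v) != len(k):
                    raise ValueError(f"block {key} length mismatch with k grid")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"block {key} contains non-finite values")

    @property
    def m_max(self) -> int:
        if self.kind == "zero":
            return 0
        if self.kind == "dipolar-toy":
            return 1
        return max((max(k[0], k[1]) for k in self.blocks), default=0)

    def _toy_channels(self, kmag):
        p = self.toy_params
        g = lambda a, w: a * np.exp(-0.5 * (kmag * w) ** 2)
        cS = g(p["a_s"], p["w_s"])
        cL = g(p["a_l"], p["w_l"])
        cT = g(p["a_t"], p["w_t"])
        return cS, (cL + 2 * cT) / 3.0, (cL - cT) / 3.0

    def channel_values(self, kmag: np.ndarray):
        """(c_S, c_Δ, c_D) evaluated at |k|, linear interpolation for tables."""
        if self.kind == "zero":
            z = np.zeros_like(kmag)
            return z, z.copy(), z.copy()
        if self.kind == "dipolar-toy":
            return self._toy_channels(kmag)
        unsupported = [
            key for key, v in self.blocks.items()
            if key not in _SUPPORTED_BLOCKS and np.any(v != 0)
        ]
        if unsupported:
            raise ValueError(
                f"kernel blocks beyond the supported m_max=1 sector: {unsupported}"
            )

        def interp(key):
            if key not in self.blocks:
                return np.zeros_like(kmag)
            v = self.blocks[key]
            re_ = np.interp(kmag, self.k_grid, v.real)
            im_ = np.interp(kmag, self.k_grid, v.imag)
            return re_ if np.all(im_ == 0) else re_ + 1j * im_

        return interp((0, 0, 0, 0, 0)), interp((1, 1, 0, 0, 0)), interp((1, 1, 2, 0, 0))

    def c000_at_zero(self) -> float:
        """ĉ^{000}_{00}(k = 0), quadratically extrapolated when absent."""
        if self.kind == "zero":
            return 0.0
        if self.kind == "dipolar-toy":
            return float(self.toy_params["a_s"])
        key = (0, 0, 0, 0, 0)
        if key not in self.blocks:
            raise ValueError("kernel lacks the (000,00) block")
        k, v = np.asarray(self.k_grid), self.blocks[key].real
        if k[0] == 0.0:
            return float(v[0])
        coef = np.polyfit(k[:3], v[:3], 2)
        return float(np.polyval(coef, 0.0))


def make_builtin_kernel(kind: str, **params) -> CorrelationKernel:
    """Analytic kernels: ``zero`` or ``dipolar-toy``.

    The dipolar toy has Gaussian channels a·exp(−k²w²/2) for the
    density (S) and the longitudinal/transverse dipole channels (L, T);
    amplitudes in Å³, widths in Å.
    """
    if kind == "zero":
        if params:
            raise ValueError("zero kernel takes no parameters")
        return CorrelationKernel("zero")
    if kind == "dipolar-toy":
        defaults = {"a_s": 0.0, "w_s": 1.0, "a_l": 0.0, "w_l": 1.0, "a_t": 0.0, "w_t": 1.0}
        unknown = set(params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown dipolar-toy parameters {sorted(unknown)}")
        defaults.update(params)
        return CorrelationKernel("dipolar-toy", toy_params=defaults)
    raise ValueError(f"unknown builtin kernel kind {kind!r}")


# ---------------------------------------------------------------------------
# Table I/O: delimited text, '#' metadata, complex values as (re, im) pairs
# ---------------------------------------------------------------------------

_COL_RE = re.compile(r"^c\((-?\d+),(-?\d+),(-?\d+);(-?\d+),(-?\d+)\)_(re|im)$")


def write_kernel_table(kernel: CorrelationKernel, path) -> None:
    if kernel.kind != "tabulated-invariants":
        # analytic kernels are sampled on a default grid before writing
        k = np.linspace(0.0, 10.0, 201)
        cS, cDel, cD = kernel.channel_values(k)
        kernel = CorrelationKernel(
            "tabulated-invariants",
            k_grid=k,
            blocks={
                (0, 0, 0, 0, 0): cS.astype(complex),
                (1, 1, 0, 0, 0): np.asarray(cDel, complex),
                (1, 1, 2, 0, 0): np.asarray(cD, complex),
            },
            metadata=dict(kernel.metadata),
        )
    keys = sorted(kernel.blocks)
    with open(path, "w") as fh:
        for mk, mv in kernel.metadata.items():
            fh.write(f"# {mk}={mv}\n")
        cols = ["k"]
        for m, n, l, mu, nu in keys:
            base = f"c({m},{n},{l};{mu},{nu})"
            cols += [f"{base}_re", f"{base}_im"]
        fh.write("\t".join(cols) + "\n")
        for i, kv in enumerate(kernel.k_grid):
            row = [f"{kv:.17g}"]
            for key in keys:
                z = kernel.blocks[key][i]
                row += [f"{z.real:.17g}", f"{z.imag:.17g}"]
            fh.write("\t".join(row) + "\n")


def load_kernel_table(path) -> CorrelationKernel:
    """Read a tabulated-invariants kernel; see :func:`write_kernel_table`."""
    metadata: dict[str, object] = {}
    header = None
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        metadata[k] = v
                continue
            if header is None:
                header = ln.split("\t")
            else:
                rows.append([float(x) for x in ln.split("\t")])
    if header is None or not rows:
        raise ValueError(f"kernel table {path} is empty")
    if header[0] != "k":
        raise ValueError("first column must be k")
    data = np.array(rows)
    kgrid = data[:, 0]
    if np.any(np.diff(kgrid) <= 0):
        raise ValueError("k grid in table is not strictly increasing")
    spec: dict[tuple, dict[str, int]] = {}
    for j, col in enumerate(header[1:], start=1):
        m = _COL_RE.match(col)
        if not m:
            raise ValueError(f"unparseable column name {col!r}")
        key = tuple(int(x) for x in m.groups()[:5])
        spec.setdefault(key, {})[m.group(6)] = j
    blocks = {}
    for key, parts in spec.items():
        if "re" not in parts or "im" not in parts:
            raise ValueError(f"block {key} missing a re/im column")
        blocks[key] = data[:, parts["re"]] + 1j * data[:, parts["im"]]
    if (0, 0, 0, 0, 0) not in blocks:
        raise ValueError("kernel table lacks the mandatory (000,00) block")
    return CorrelationKernel("tabulated-invariants", kgrid, blocks, metadata=metadata)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


def convolve_kernel(
    kernel: CorrelationKernel,
    delta_values: np.ndarray,
    grid: SpatialGrid,
    quad: OrientationQuadrature,
) -> np.ndarray:
    """γ(r, Ω) = (c ★ Δρ)(r, Ω), FFT in space, channel algebra in Ω.

    The Δ and D dipole channels couple only to the polarization density
    P(r) = ∫ u(Ω) Δρ(r, Ω) dΩ; the isotropic channel to the number
    density deviation.  At k = 0 the longitudinal/transverse split is
    direction-free by convention (k̂ ≡ 0 there).
    """
    expected = grid.shape + (quad.n_orientations,)
    if delta_values.shape != expected:
        raise ValueError(f"field shape {delta_values.shape} != {expected}")
    gamma = np.zeros(expected)
    if kernel.kind == "zero":
        return gamma
    if kernel.kind == "tabulated-invariants":
        pass  # channel_values validates block support below

    dV = grid.voxel_volume
    w = quad.weights
    u = quad.molecular_axes()  # (M, 3)
    M = quad.n_orientations

    # generalized moments of Δρ in k-space (continuum FT units)
    rho_k = [np.fft.fftn(delta_values[..., m]) * dV for m in range(M)]
    n_k = np.zeros(grid.shape, complex)
    P_k = np.zeros(grid.shape + (3,), complex)
    for m in range(M):
        n_k += w[m] * rho_k[m]
        for a in range(3):
            P_k[..., a] += w[m] * u[m, a] * rho_k[m]
    del rho_k

    k = grid.kvectors()
    kmag = np.sqrt(np.einsum("xyzi,xyzi->xyz", k, k))
    khat = np.zeros_like(k)
    nzero = kmag > 0
    khat[nzero] = k[nzero] / kmag[nzero][..., None]

    cS, cDel, cD = kernel.channel_values(kmag)
    kP = np.einsum("xyzi,xyzi->xyz", khat.astype(complex), P_k)

    for m in range(M):
        uP = np.einsum("i,xyzi->xyz", u[m], P_k)
        uk = np.einsum("i,xyzi->xyz", u[m], khat)
        g_k = cS * n_k + cDel * uP + cD * (3.0 * uk * kP - uP)
        gamma[..., m] = np.fft.ifftn(g_k).real / dV
    return gamma


def kernel_bulk_pressure(kernel: CorrelationKernel, solvent) -> float:
    """HNC-grade bulk pressure estimate, kJ·mol⁻¹·Å⁻³.

    P = n k_B T − (k_B T / 2) n² ĉ₀₀₀(0); used only to size the
    post-hoc pressure correction, which also accepts a user value.
    """
    n = solvent.n_bulk
    kT = KB * solvent.temperature
    return n * kT - 0.5 * kT * n * n * kernel.c000_at_zero()
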