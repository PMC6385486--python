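"""Independent reference implementations used only by the tests.

Everything here deliberately avoids the package's FFT convolution path:
kernels are tabulated in real space by explicit discrete Fourier sums
and convolutions are O(N²) double sums, so agreement with the package
is a genuine two-route check.
"""

import numpy as np


def channel_chat(kernel, kvecs):
    """ĉ(k, Ω₁, Ω₂) on explicit k vectors, shape (M, M, K)."""
    kmag = np.linalg.norm(kvecs, axis=1)
    khat = np.zeros_like(kvecs)
    nz = kmag > 0
    khat[nz] = kvecs[nz] / kmag[nz][:, None]
    return kmag, khat


def brute_force_gamma(kernel, delta_values, grid, quad):
    """γ = c ★ Δρ by explicit DFT of the kernel and an O(N²) double sum."""
    k = grid.kvectors().reshape(-1, 3)
    kmag, khat = channel_chat(kernel, k)
    cS, cDel, cD = kernel.channel_values(kmag)
    u = quad.molecular_axes()
    uk = u @ khat.T
    uu = u @ u.T
    chat = (
        cS[None, None, :]
        + cDel[None, None, :] * uu[:, :, None]
        + cD[None, None, :] * (3 * uk[:, None, :] * uk[None, :, :] - uu[:, :, None])
    )
    coords = grid.coordinates().reshape(-1, 3)
    phase = np.exp(1j * (coords @ k.T))  # (N, K)
    # real-space periodic kernel c(r_a, Ω_m; r_b, Ω_n), then the double sum
    c_real = np.einsum("ak,mnk,bk->ambn", phase, chat, phase.conj()).real / grid.volume
    d_flat = delta_values.reshape(len(coords), quad.n_orientations)
    w = quad.weights
    dV = grid.voxel_volume
    g = np.einsum("ambn,bn,n->am", c_real, d_flat, w) * dV
    return g.reshape(delta_values.shape)


def dense_quadratic_solution(kernel, V, solvent, grid, quad):
    """Direct solve of the linear stationarity equations of the quadratic model."""
    kT = solvent.kT
    rho_b = solvent.rho_bulk(quad)
    N = grid.n_voxels * quad.n_orientations
    mvec = np.broadcast_to(grid.voxel_volume * quad.weights, V.values.shape).ravel()
    k = grid.kvectors().reshape(-1, 3)
    kmag, khat = channel_chat(kernel, k)
    cS, cDel, cD = kernel.channel_values(kmag)
    u = quad.molecular_axes()
    uk = u @ khat.T
    uu = u @ u.T
    chat = (
        cS[None, None, :]
        + cDel[None, None, :] * uu[:, :, None]
        + cD[None, None, :] * (3 * uk[:, None, :] * uk[None, :, :] - uu[:, :, None])
    )
    coords = grid.coordinates().reshape(-1, 3)
    phase = np.exp(1j * (coords @ k.T))
    c_real = np.einsum("ak,mnk,bk->ambn", phase, chat, phase.conj()).real / grid.volume
    C = c_real.reshape(N, N)
    A = kT * np.eye(N) / rho_b - kT * C * mvec[None, :]
    d = np.linalg.solve(A, -V.values.ravel())
    return d.reshape(V.values.shape)
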