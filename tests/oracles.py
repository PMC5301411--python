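"""Independent brute-force oracles for solver verification.

Everything here is built from first principles — explicit centred DFT
matrices and dense linear algebra — deliberately avoiding the package's
FFT-based operator code, so that agreement between the two routes is a
meaningful check.
"""

from __future__ import annotations

import numpy as np


def dft1c(n: int) -> np.ndarray:
    """Centred unitary 1-D DFT matrix (origin at index n//2 on both axes)."""
    k = np.arange(n) - n // 2
    r = np.arange(n) - n // 2
    return np.exp(-2j * np.pi * np.outer(k, r) / n) / np.sqrt(n)


def dense_normal_solve(sens_maps: np.ndarray, W: np.ndarray, Vb: np.ndarray,
                       Y: np.ndarray) -> np.ndarray:
    """Direct dense solve of the subspace-SENSE normal equations.

    Builds ``A^H A`` and ``A^H d`` explicitly from the centred DFT matrix
    ``F = kron(F_ny, F_nx)``: for each temporal column c with sampled ky set
    ``Omega_c``, the coil-summed block is ``(F_sel^H F_sel) * (S^H S)``
    (elementwise), combined across columns through the rank-one temporal
    factors ``outer(conj(v_c), v_c)``. Returns the minimum-norm solution
    ``U`` of shape (N, L).

    Parameters: ``sens_maps`` (Nc, ny, nx); ``W`` (n_cols, ny) 0/1 sampling
    indicators; ``Vb`` (L, n_cols) temporal basis; ``Y`` (Nc, n_cols, ny,
    nx) zero-filled measured k-space.
    """
    Nc, ny, nx = sens_maps.shape
    N = ny * nx
    L, n_cols = Vb.shape
    F = np.kron(dft1c(ny), dft1c(nx))            # (N, N), row-major k index
    S = sens_maps.reshape(Nc, N)
    Q = S.conj().T @ S                           # Q[n,n'] = sum_i S_i*[n] S_i[n']

    AHA = np.zeros((N * L, N * L), dtype=np.complex128)
    b = np.zeros(N * L, dtype=np.complex128)
    for c in range(n_cols):
        kys = np.flatnonzero(W[c] > 0)
        if kys.size == 0:
            continue
        rows = F[(kys[:, None] * nx + np.arange(nx)[None, :]).ravel()]
        G = rows.conj().T @ rows                 # F_sel^H F_sel, (N, N)
        Qc = G * Q
        vc = Vb[:, c]
        Rc = np.outer(vc.conj(), vc)
        AHA += np.kron(Qc, Rc)
        # A^H d for this column: coil-combined F^H on the zero-filled data
        g = np.zeros(N, dtype=np.complex128)
        for i in range(Nc):
            g += S[i].conj() * (F.conj().T @ Y[i, c].ravel())
        b += np.outer(g, vc.conj()).ravel()
    u, *_ = np.linalg.lstsq(AHA, b, rcond=None)
    return u.reshape(N, L)
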