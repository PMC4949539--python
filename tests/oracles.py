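"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive the same physics through different machinery:
the EPG oracle propagates one explicit dense state matrix per echo interval
over all coherence orders, and the spherical oracle integrates on a dense
latitude-longitude grid.  Neither shares code with the package internals.
"""

import numpy as np


def epg_dense_oracle(flip_angle, t2, t1, te_spacing, n_echoes):
    """CPMG echo amplitudes via explicit dense state-transition matrices.

    State vector stacks (F+_0..F+_K, F-_0..F-_K, Z_0..Z_K); one full echo
    interval is the single dense matrix  E S R S E  (relax half, dephase,
    rotate, dephase, relax half) applied repeatedly.
    """
    K = n_echoes + 1
    dim = 3 * K

    e2 = np.exp(-te_spacing / (2.0 * t2))
    e1 = np.exp(-te_spacing / (2.0 * t1))
    E = np.diag(np.concatenate([np.full(2 * K, e2), np.full(K, e1)]))

    S = np.zeros((dim, dim))
    # F+ orders shift up; order 0 of F+ is fed by F- order 1
    for k in range(1, K):
        S[k, k - 1] = 1.0
    S[0, K + 1] = 1.0
    # F- orders shift down
    for k in range(K - 1):
        S[K + k, K + k + 1] = 1.0
    # Z untouched
    for k in range(K):
        S[2 * K + k, 2 * K + k] = 1.0

    a = np.deg2rad(flip_angle)
    c2, s2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    sa, ca = np.sin(a), np.cos(a)
    R = np.zeros((dim, dim))
    for k in range(K):
        idx = [k, K + k, 2 * K + k]
        block = np.array([[c2, s2, sa], [s2, c2, -sa], [-sa / 2, sa / 2, ca]])
        for i in range(3):
            for j in range(3):
                R[idx[i], idx[j]] = block[i, j]

    period = E @ S @ R @ S @ E
    state = np.zeros(dim)
    state[0] = 1.0
    echoes = np.empty(n_echoes)
    for n in range(n_echoes):
        state = period @ state
        echoes[n] = state[0]
    return echoes


def sphere_quadrature_oracle(func, n_theta=200):
    """Integral over the unit sphere of ``func(nx, ny, nz)`` on a dense
    latitude-longitude grid (2 * n_theta^2 points)."""
    th = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    ph = np.arange(2 * n_theta) * 2 * np.pi / (2 * n_theta)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    w = np.sin(TH) * (np.pi / n_theta) * (2 * np.pi / (2 * n_theta))
    nx = np.sin(TH) * np.cos(PH)
    ny = np.sin(TH) * np.sin(PH)
    nz = np.cos(TH)
    return float(np.sum(w * func(nx, ny, nz)))
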