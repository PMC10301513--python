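"""Trivariate cubic monomial basis shared by the phantom generator and the
phase-offset correction.

The basis is the 20 monomials ``x^i y^j z^k`` with total degree ``i+j+k <= 3``
evaluated on voxel coordinates normalised to ``[-1, 1]`` per axis, which keeps
the ordinary-least-squares design matrix well conditioned.  The ordering is
fixed (ascending total degree, then lexicographic in the exponent triple) so
that coefficient vectors are interchangeable across modules and serialisable.
"""

from __future__ import annotations

import numpy as np

N_COEFFS = 20


def monomial_exponents() -> list[tuple[int, int, int]]:
    """The fixed (i, j, k) exponent ordering of the 20 cubic monomials."""
    exps = [
        (i, j, k)
        for d in range(4)
        for i in range(d + 1)
        for j in range(d - i + 1)
        for k in (d - i - j,)
    ]
    assert len(exps) == N_COEFFS
    return exps


def normalized_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis voxel-index coordinates mapped affinely onto [-1, 1]."""
    axes = []
    for n in shape:
        if n > 1:
            axes.append(np.linspace(-1.0, 1.0, n))
        else:
            axes.append(np.zeros(1))
    return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


def design_matrix(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Design matrix (n_points, 20) of the cubic basis at normalised points."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    cols = [x**i * y**j * z**k for i, j, k in monomial_exponents()]
    return np.stack(cols, axis=1)


def evaluate(coeffs: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Evaluate a 20-coefficient cubic polynomial on a full normalised grid."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (N_COEFFS,):
        raise ValueError(f"expected {N_COEFFS} coefficients, got {coeffs.shape}")
    xg, yg, zg = normalized_coords(shape)
    out = np.zeros(shape, dtype=float)
    for c, (i, j, k) in zip(coeffs, monomial_exponents()):
        if c != 0.0:
            out += c * xg**i * yg**j * zg**k
    return out
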