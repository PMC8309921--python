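"""Singular-vector basis of non-fluorescent training spectra.

The retrieval expresses the non-fluorescent part of a measured spectrum in a
basis of right-singular vectors of a training matrix (scenes as rows,
channels as columns) of spectra that contain no vegetation signal.  The
leading vector v_1 carries the dominant spectrum shape — in raw radiance
units, because the forward model multiplies v_1 by a wavelength polynomial —
so the training matrix is neither mean-centered nor normalized before
decomposition.

Sign convention: each vector is flipped so that its inner product with the
mean training spectrum is >= 0; exact ties flip so that the largest-magnitude
element is positive.  This makes bases reproducible across linear-algebra
backends.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synth import SpectralGrid

_ORTHO_TOL = 1e-10


@dataclasses.dataclass
class SingularBasis:
    """Ordered singular vectors with singular values and variance fractions.

    ``vectors`` has shape (m, n_channels) with unit-norm rows sorted by
    non-increasing singular value.  ``explained_variance`` holds
    p_j = s_j^2 / sum_k s_k^2 computed over the *full* decomposition, so the
    fractions of a complete basis sum to 1.
    """

    grid: SpectralGrid
    vectors: np.ndarray
    singular_values: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        s = np.asarray(self.singular_values, dtype=float)
        p = np.asarray(self.explained_variance, dtype=float)
        if v.shape[1] != self.grid.n_channels:
            raise ValueError("vectors and grid disagree on the number of channels")
        if s.shape != (v.shape[0],) or p.shape != (v.shape[0],):
            raise ValueError("singular_values/explained_variance must match vector count")
        if np.any(np.diff(s) > 0):
            raise ValueError("singular values must be non-increasing")
        if np.any(s < 0):
            raise ValueError("singular values must be non-negative")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("explained variance fractions must lie in [0, 1]")
        self.vectors = v
        self.singular_values = s
        self.explained_variance = p

    @property
    def n_vectors(self) -> int:
        return int(self.vectors.shape[0])


def _fix_signs(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for j in range(out.shape[0]):
        dot = float(out[j] @ reference)
        if dot < 0:
            out[j] = -out[j]
        elif dot == 0.0:
            if out[j][np.argmax(np.abs(out[j]))] < 0:
                out[j] = -out[j]
    return out


def compute_svs(
    training_matrix: np.ndarray, grid: SpectralGrid, n_keep: int | None = None
) -> SingularBasis:
    """SVD of the training matrix; returns the leading right-singular vectors.

    Parameters
    ----------
    training_matrix
        (n_scenes, n_channels) radiance matrix, n_scenes >= 2, not all zero.
    grid
        The wavelength axis shared by the training spectra.
    n_keep
        Number of vectors to retain (default: all of min(n_scenes, n_channels)).
        Explained-variance fractions are computed before truncation, so kept
        fractions sum to 1 only for a complete basis.
    """
    x = np.atleast_2d(np.asarray(training_matrix, dtype=float))
    n_scenes, n_chan = x.shape
    if n_scenes < 2 or n_chan < 2:
        raise ValueError("training matrix must be at least 2 x 2")
    if n_chan != grid.n_channels:
        raise ValueError("training matrix and grid disagree on the number of channels")
    if not np.any(x):
        raise ValueError("training matrix is identically zero")
    m_full = min(n_scenes, n_chan)
    if n_keep is None:
        n_keep = m_full
    if not (1 <= n_keep <= m_full):
        raise ValueError(f"n_keep must be in [1, {m_full}], got {n_keep}")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    p = s**2 / np.sum(s**2)
    vectors = _fix_signs(vt, x.mean(axis=0))
    return SingularBasis(
        grid=grid,
        vectors=vectors[:n_keep],
        singular_values=s[:n_keep],
        explained_variance=p[:n_keep],
    )


def project(basis: SingularBasis, spectrum: np.ndarray) -> np.ndarray:
    """Coefficients omega_j = <v_j, spectrum> of a spectrum on the basis grid.

    Because the vectors are orthonormal, sum_j omega_j v_j is the L2-optimal
    reconstruction within the span and the residual is orthogonal to every
    kept vector.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (basis.grid.n_channels,):
        raise ValueError(
            f"spectrum has {spectrum.shape} channels, basis grid has "
            f"{basis.grid.n_channels}"
        )
    return basis.vectors @ spectrum
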