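"""Linear forward model for in-window TOA radiance.

The measured radiance inside the retrieval window is modelled as

    L(lambda) = v_1(lambda) * sum_{i=0..nP} a_i lamhat^i
                + sum_{j=2..nv} omega_j v_j(lambda)
                + Fs * h_F(lambda)

i.e. the leading singular vector modulated by a low-order wavelength
polynomial (the spectrally smooth surface/atmosphere contribution), a free
linear combination of the remaining singular vectors (high-frequency
variability), and a Gaussian fluorescence emission shape h_F peaking at
740 nm.  Ground-to-sensor transmittance is deliberately absent: in a window
free of atmospheric features it is indistinguishable from 1, and when the
simulator injects O2-like absorption the resulting model mismatch is the
point of the window-sensitivity experiment.

The polynomial is evaluated on lamhat = (lambda - mid(window)) / width(window)
rather than raw nm: raw wavelengths near 775 with order-1 terms make
near-collinear columns, and the affine reparametrization changes the a_i but
not the fitted Fs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np

from .basis import SingularBasis
from .synth import DEFAULT_WINDOW

logger = logging.getLogger("sifsvd.forward")

FLUOR_PEAK_NM = 740.0


def gaussian_hf(
    wavelengths: np.ndarray | float,
    sigma: float = 30.0,
    phi: float = 1.0,
    center: float = FLUOR_PEAK_NM,
) -> np.ndarray | float:
    """Gaussian fluorescence emission shape phi * exp(-(lambda-center)^2 / (2 sigma^2)).

    Peak value ``phi`` at ``center`` (740 nm by default), symmetric about the
    center; ``sigma`` (nm) sets the width of the far-red emission feature.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    lam = np.asarray(wavelengths, dtype=float)
    out = phi * np.exp(-((lam - center) ** 2) / (2.0 * sigma**2))
    return float(out) if np.isscalar(wavelengths) else out


@dataclasses.dataclass(frozen=True)
class RetrievalConfig:
    """Tunable parameters of the retrieval.

    Defaults follow the reference configuration for the O2-A channel:
    window 771–778 nm (Fraunhofer lines only), first-order polynomial,
    singular-vector counts 2..8 offered to the BIC, Gaussian width
    sigma = 30 nm with peak height phi = 1, and SIF reported at 775 nm.
    ``nv`` counts singular vectors inclusive of v_1, so nv = 5 means four
    free-omega columns.  ``rss_squared_weights`` selects the
    sum-of-(weight*residual)^2 convention for the residual sum of squares;
    the alternative sum-of-weight*residual^2 is available for comparison.
    """

    window: tuple[float, float] = DEFAULT_WINDOW
    poly_order: int = 1
    nv_candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    sigma: float = 30.0
    phi: float = 1.0
    fluor_center: float = FLUOR_PEAK_NM
    lambda_ref: float = 775.0
    weighting: bool = True
    rss_squared_weights: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window must satisfy lo < hi, got {self.window}")
        if self.poly_order < 0:
            raise ValueError("poly_order (nP) must be >= 0")
        if not self.nv_candidates or any(nv < 1 for nv in self.nv_candidates):
            raise ValueError("nv_candidates must be a non-empty set of integers >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.phi > 0:
            raise ValueError("phi must be > 0")

    def replace(self, **changes) -> "RetrievalConfig":
        return dataclasses.replace(self, **changes)

    def n_coefficients(self, nv: int) -> int:
        """Free-parameter count k = (nP + 1) + (nv - 1) + 1."""
        return (self.poly_order + 1) + (nv - 1) + 1


@dataclasses.dataclass
class DesignMatrix:
    """Column blocks [v_1 * lamhat^0..nP | v_2..v_nv | h_F] on the window grid."""

    matrix: np.ndarray
    column_labels: tuple[str, ...]
    wavelengths: np.ndarray
    window_mask: np.ndarray
    poly_order: int
    nv: int

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def hf_index(self) -> int:
        return self.n_columns - 1


def build_design_matrix(
    basis: SingularBasis, config: RetrievalConfig, nv: int
) -> DesignMatrix:
    """Assemble the forward-model design matrix for ``nv`` singular vectors."""
    if not (1 <= nv <= basis.n_vectors):
        raise ValueError(f"nv must be in [1, {basis.n_vectors}], got {nv}")
    mask = basis.grid.window_mask(*config.window)
    if not mask.any():
        raise ValueError(
            f"retrieval window {config.window} contains no channels of the grid"
        )
    lam = basis.grid.wavelengths[mask]
    lo, hi = config.window
    lam_hat = (lam - 0.5 * (lo + hi)) / (hi - lo)

    columns: list[np.ndarray] = []
    labels: list[str] = []
    v1 = basis.vectors[0, mask]
    for i in range(config.poly_order + 1):
        columns.append(v1 * lam_hat**i)
        labels.append(f"v1*lamhat^{i}")
    for j in range(2, nv + 1):
        columns.append(basis.vectors[j - 1, mask])
        labels.append(f"v{j}")
    columns.append(gaussian_hf(lam, config.sigma, config.phi, config.fluor_center))
    labels.append("hF")

    matrix = np.column_stack(columns)
    logger.debug(
        "design matrix nv=%d: %d channels x %d columns, cond=%.3e",
        nv,
        matrix.shape[0],
        matrix.shape[1],
        np.linalg.cond(matrix),
    )
    return DesignMatrix(
        matrix=matrix,
        column_labels=tuple(labels),
        wavelengths=lam,
        window_mask=mask,
        poly_order=config.poly_order,
        nv=nv,
    )


def predict_radiance(dm: DesignMatrix, coefficients: Iterable[float]) -> np.ndarray:
    """Forward-evaluate the linear model: matrix @ coefficients."""
    c = np.asarray(list(coefficients) if not isinstance(coefficients, np.ndarray) else coefficients, dtype=float)
    if c.shape != (dm.n_columns,):
        raise ValueError(f"expected {dm.n_columns} coefficients, got {c.shape}")
    return dm.matrix @ c
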