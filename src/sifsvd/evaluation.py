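"""Comparison statistics and sensitivity sweeps.

The statistics are the squared Pearson correlation (R^2), the mean difference
(bias, retrieved minus reference) and the root-mean-square difference (RMSE).
The sweeps rerun the retrieval over a grid of one tuned parameter — Gaussian
emission width sigma, number of singular vectors nv, or spectral window —
and score the retrieved fluorescence amplitudes against the simulator truth.
Scoring against truth turns the published product comparisons into
parameter-recovery experiments: the qualitative orderings (best sigma at the
generating width, best nv at the generating pattern count, clean window
beating O2-contaminated windows) are the testable content.

All sweeps are pure functions of their inputs; rerunning reproduces the
tables bitwise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import SingularBasis
from .forward import RetrievalConfig
from .retrieval import retrieve_many
from .synth import SceneSet


@dataclasses.dataclass(frozen=True)
class ComparisonStats:
    """R^2 / bias / RMSE of retrieved (x) against reference (y) values.

    ``r2`` is NaN (flagged missing) when either side has zero variance.
    """

    r2: float
    bias: float
    rmse: float
    n: int


def comparison_stats(x: np.ndarray, y: np.ndarray) -> ComparisonStats:
    """Squared-Pearson R^2, mean difference, and RMS difference of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("comparison inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        r2 = float("nan")
    else:
        r2 = float((dx @ dy) ** 2 / (sxx * syy))
    diff = x - y
    return ComparisonStats(
        r2=r2,
        bias=float(diff.mean()),
        rmse=float(np.sqrt(np.mean(diff**2))),
        n=int(x.size),
    )


def _score(scenes: SceneSet, fs_hat: np.ndarray) -> ComparisonStats:
    ok = np.isfinite(fs_hat)
    return comparison_stats(fs_hat[ok], scenes.fs_true[ok])


def _fs_and_residuals(
    scenes: SceneSet,
    basis: SingularBasis,
    config: RetrievalConfig,
    nv: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    results = retrieve_many(scenes.spectra, basis, config, snr=scenes.snr, nv=nv)
    fs_hat = np.array([r.fs for r in results])
    mean_abs_resid = np.array(
        [np.mean(np.abs(r.residuals)) if r.valid else np.nan for r in results]
    )
    return fs_hat, mean_abs_resid


def sweep_sigma(
    scenes: SceneSet,
    basis: SingularBasis,
    config: RetrievalConfig,
    sigma_values: Sequence[float],
) -> pd.DataFrame:
    """Recovery statistics of the retrieved amplitude per emission width sigma."""
    if len(sigma_values) < 1:
        raise ValueError("sweep needs at least one sigma value")
    rows = []
    for sigma in sigma_values:
        fs_hat, _ = _fs_and_residuals(scenes, basis, config.replace(sigma=float(sigma)))
        stats = _score(scenes, fs_hat)
        rows.append({"sigma": float(sigma), **dataclasses.asdict(stats)})
    return pd.DataFrame(rows)


def sweep_nsv(
    scenes: SceneSet,
    basis: SingularBasis,
    config: RetrievalConfig,
    nv_values: Sequence[int],
) -> pd.DataFrame:
    """Recovery statistics per fixed singular-vector count (BIC disabled).

    Also reports the mean absolute fit residual per nv, the spectral
    reconstruction-accuracy analogue.
    """
    if len(nv_values) < 1:
        raise ValueError("sweep needs at least one nv value")
    rows = []
    for nv in nv_values:
        fs_hat, resid = _fs_and_residuals(scenes, basis, config, nv=int(nv))
        stats = _score(scenes, fs_hat)
        rows.append(
            {
                "nv": int(nv),
                **dataclasses.asdict(stats),
                "mean_abs_residual": float(np.nanmean(resid)),
            }
        )
    return pd.DataFrame(rows)


def sweep_window(
    scenes: SceneSet,
    basis: SingularBasis,
    config: RetrievalConfig,
    windows: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Recovery statistics per retrieval window.

    Each window must lie within the grid extent.  With O2-like absorption
    present in the scenes but absent from the forward model, windows that
    reach into the contaminated region score worse than the clean window.
    """
    if len(windows) < 1:
        raise ValueError("sweep needs at least one window")
    wl = scenes.grid.wavelengths
    rows = []
    for lo, hi in windows:
        if lo < wl[0] or hi > wl[-1] + scenes.grid.sampling_step:
            raise ValueError(f"window ({lo}, {hi}) is not contained in the grid")
        fs_hat, _ = _fs_and_residuals(
            scenes, basis, config.replace(window=(float(lo), float(hi)))
        )
        stats = _score(scenes, fs_hat)
        rows.append({"window_min": float(lo), "window_max": float(hi), **dataclasses.asdict(stats)})
    return pd.DataFrame(rows)
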