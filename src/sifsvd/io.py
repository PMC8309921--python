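"""File formats, configuration loading, and run manifests.

Two on-disk spectrum formats are supported:

* plain delimited text (``.csv``/``.tsv``/``.txt``) with header columns
  ``wavelength_nm, radiance`` and optional ``snr`` — one sounding per file,
  convenient for small fixtures;
* a self-describing netCDF container (``.nc``, NETCDF3 via the scipy
  backend) with dimensions ``(sounding, channel)`` and variables
  ``wavelength(channel)``, ``radiance(sounding, channel)``, optional
  ``snr(sounding, channel)`` and per-sounding ``fs_true`` where the simulator
  knows the truth.  Both carry a ``schema_version`` field.

Retrieval/scene configuration is TOML; unknown keys are rejected with the
list of valid keys so typos fail loudly.  Every CLI run writes a JSON
manifest (tool version, config snapshot, input checksums, seed, timestamp)
next to its output.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .forward import RetrievalConfig
from .synth import SceneSet, SNRModel, SolarModel, SpectralGrid

logger = logging.getLogger("sifsvd.io")

SCHEMA_VERSION = "1"

_TEXT_SUFFIXES = {".csv", ".tsv", ".txt", ".dat"}


@dataclasses.dataclass
class Soundings:
    """In-memory batch of soundings: shared grid, per-sounding radiance rows."""

    grid: SpectralGrid
    radiance: np.ndarray
    snr: np.ndarray | None = None
    fs_true: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.radiance = np.atleast_2d(np.asarray(self.radiance, dtype=float))
        if self.radiance.shape[1] != self.grid.n_channels:
            raise ValueError("radiance rows must align with the wavelength axis")
        if self.ids is None:
            self.ids = [f"{i:06d}" for i in range(self.radiance.shape[0])]

    @property
    def n_soundings(self) -> int:
        return int(self.radiance.shape[0])


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix == ".tsv" else ","


def read_spectra(path: str | Path) -> Soundings:
    """Read soundings from delimited text (one sounding) or a netCDF container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".nc":
        ds = xr.open_dataset(path, engine="scipy")
        try:
            grid = SpectralGrid(
                ds["wavelength"].values,
                sampling_step=float(ds.attrs.get("sampling_step_nm", 0.044)),
            )
            radiance = np.atleast_2d(ds["radiance"].values)
            snr = np.atleast_2d(ds["snr"].values) if "snr" in ds else None
            fs_true = ds["fs_true"].values if "fs_true" in ds else None
        finally:
            ds.close()
        return Soundings(grid=grid, radiance=radiance, snr=snr, fs_true=fs_true)

    frame = pd.read_csv(path, sep=_delimiter_for(path), float_precision="round_trip")
    for col in ("wavelength_nm", "radiance"):
        if col not in frame.columns:
            raise ValueError(
                f"{path}: missing required column '{col}' "
                f"(found {list(frame.columns)})"
            )
    try:
        grid = SpectralGrid(frame["wavelength_nm"].to_numpy())
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    snr = frame["snr"].to_numpy()[None, :] if "snr" in frame.columns else None
    return Soundings(grid=grid, radiance=frame["radiance"].to_numpy()[None, :], snr=snr)


def write_spectra(path: str | Path, soundings: Soundings) -> None:
    """Write soundings to the format implied by the file suffix."""
    path = Path(path)
    if path.suffix == ".nc":
        data: dict[str, Any] = {
            "wavelength": ("channel", soundings.grid.wavelengths),
            "radiance": (("sounding", "channel"), soundings.radiance),
        }
        if soundings.snr is not None:
            data["snr"] = (("sounding", "channel"), np.broadcast_to(soundings.snr, soundings.radiance.shape))
        if soundings.fs_true is not None:
            data["fs_true"] = ("sounding", np.asarray(soundings.fs_true, dtype=float))
        ds = xr.Dataset(
            data,
            attrs={
                "schema_version": SCHEMA_VERSION,
                "sampling_step_nm": soundings.grid.sampling_step,
            },
        )
        ds.to_netcdf(path, engine="scipy")
    elif path.suffix in _TEXT_SUFFIXES:
        if soundings.n_soundings != 1:
            raise ValueError("delimited text holds exactly one sounding; use .nc for batches")
        frame = pd.DataFrame(
            {"wavelength_nm": soundings.grid.wavelengths, "radiance": soundings.radiance[0]}
        )
        if soundings.snr is not None:
            frame["snr"] = np.asarray(soundings.snr)[0]
        frame.to_csv(path, sep=_delimiter_for(path), index=False)
    else:
        raise ValueError(f"unsupported spectra format: {path.suffix}")


def scene_set_to_soundings(scenes: SceneSet) -> Soundings:
    snr = None
    if scenes.snr is not None:
        snr = scenes.snr.at(scenes.spectra)
    return Soundings(
        grid=scenes.grid, radiance=scenes.spectra, snr=snr, fs_true=scenes.fs_true
    )


def soundings_to_scene_set(soundings: Soundings, snr: SNRModel | None = None) -> SceneSet:
    """View a soundings batch as a SceneSet for the sweep drivers.

    Requires per-sounding truth (``fs_true``) in the file.
    """
    if soundings.fs_true is None:
        raise ValueError("sweeps need ground truth; the input file has no fs_true")
    return SceneSet(
        grid=soundings.grid,
        spectra=soundings.radiance,
        fs_true=np.asarray(soundings.fs_true, dtype=float),
        snr=snr,
    )


def write_basis(path: str | Path, basis) -> None:
    ds = xr.Dataset(
        {
            "wavelength": ("channel", basis.grid.wavelengths),
            "vectors": (("component", "channel"), basis.vectors),
            "singular_values": ("component", basis.singular_values),
            "explained_variance": ("component", basis.explained_variance),
        },
        attrs={
            "schema_version": SCHEMA_VERSION,
            "sampling_step_nm": basis.grid.sampling_step,
        },
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_basis(path: str | Path):
    from .basis import SingularBasis

    ds = xr.open_dataset(Path(path), engine="scipy")
    try:
        grid = SpectralGrid(
            ds["wavelength"].values,
            sampling_step=float(ds.attrs.get("sampling_step_nm", 0.044)),
        )
        basis = SingularBasis(
            grid=grid,
            vectors=ds["vectors"].values,
            singular_values=ds["singular_values"].values,
            explained_variance=ds["explained_variance"].values,
        )
    finally:
        ds.close()
    return basis


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_RETRIEVAL_KEYS = {
    "window",
    "poly_order",
    "nv_candidates",
    "sigma",
    "phi",
    "fluor_center",
    "lambda_ref",
    "weighting",
    "rss_squared_weights",
}

_SCENE_KEYS = {
    "n_scenes",
    "fs_range",
    "sigma_f",
    "phi",
    "mu0_range",
    "shift_range",
    "width_scale_range",
    "o2_depth_range",
    "snr_offset",
    "snr_slope",
}

_SOLAR_KEYS = {"continuum_coeffs", "lines"}

_SWEEP_KEYS = {"kind", "sigma_values", "nv_values", "windows"}


def _reject_unknown(section: dict, valid: set[str], name: str) -> None:
    unknown = set(section) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{name}]; valid keys: {sorted(valid)}"
        )


def load_retrieval_config(path: str | Path | None) -> RetrievalConfig:
    """Retrieval configuration from TOML; missing file/keys fall to defaults."""
    if path is None:
        return RetrievalConfig()
    raw = tomllib.loads(Path(path).read_text())
    section = raw.get("retrieval", {})
    _reject_unknown(section, _RETRIEVAL_KEYS, "retrieval")
    kwargs: dict[str, Any] = dict(section)
    if "window" in kwargs:
        kwargs["window"] = tuple(float(v) for v in kwargs["window"])
    if "nv_candidates" in kwargs:
        kwargs["nv_candidates"] = tuple(int(v) for v in kwargs["nv_candidates"])
    return RetrievalConfig(**kwargs)


def load_scene_config(path: str | Path | None) -> tuple[dict[str, Any], SolarModel]:
    """Scene-set and solar-model settings for the simulator CLI."""
    raw = tomllib.loads(Path(path).read_text()) if path is not None else {}
    scene = dict(raw.get("scene", {}))
    _reject_unknown(scene, _SCENE_KEYS, "scene")
    solar_raw = dict(raw.get("solar", {}))
    _reject_unknown(solar_raw, _SOLAR_KEYS, "solar")

    solar_kwargs: dict[str, Any] = {}
    if "continuum_coeffs" in solar_raw:
        solar_kwargs["continuum_coeffs"] = tuple(float(v) for v in solar_raw["continuum_coeffs"])
    if "lines" in solar_raw:
        solar_kwargs["lines"] = tuple(tuple(float(v) for v in line) for line in solar_raw["lines"])
    solar = SolarModel(**solar_kwargs)

    snr = SNRModel(
        offset=float(scene.pop("snr_offset", 300.0)),
        slope=float(scene.pop("snr_slope", 0.0)),
    )
    kwargs: dict[str, Any] = {"snr": snr, "n_scenes": int(scene.pop("n_scenes", 100))}
    for key in ("fs_range", "mu0_range", "shift_range", "width_scale_range", "o2_depth_range"):
        if key in scene:
            kwargs[key] = tuple(float(v) for v in scene.pop(key))
    kwargs.update({k: float(v) for k, v in scene.items()})
    return kwargs, solar


def load_sweep_config(path: str | Path) -> dict[str, Any]:
    raw = tomllib.loads(Path(path).read_text())
    section = dict(raw.get("sweep", {}))
    _reject_unknown(section, _SWEEP_KEYS, "sweep")
    if "windows" in section:
        section["windows"] = [tuple(float(v) for v in w) for w in section["windows"]]
    return section


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    params: dict[str, Any],
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Write a JSON reproducibility manifest next to a CLI output file."""
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "tool": "sifsvd",
        "version": __version__,
        "command": command,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": params,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in inputs if Path(p).exists()
        ],
    }
    manifest_path = out_path.with_name(out_path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest_path
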