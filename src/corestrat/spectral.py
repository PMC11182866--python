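"""Hyperspectral chloropigment indexing of split sediment-core faces.

The relative absorption band depth index RABD(655-680) measures the depth
of the chlorophyll absorption trough in visible reflectance spectra and
serves as a fast, non-destructive proxy for total chloropigments (TChl:
chlorophyll a, b and coloured derivatives).  For each spectrum the
continuum across the trough is reconstructed by band-count-weighted
interpolation between two shoulder wavelengths (defaults 590 and 730 nm)
and the index is continuum / R(trough minimum); a flat spectrum yields
exactly 1, deeper troughs yield larger values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectralCube", "rabd_index", "rabd_series", "moving_average",
           "bin_by_depth"]


@dataclass
class SpectralCube:
    """Per-depth reflectance spectra on a common wavelength grid.

    ``reflectance[i, j]`` is the reflectance (unitless, in (0, 1]) of the
    scan row at ``depth[i]`` cm and ``wavelength[j]`` nm.  The wavelength
    grid must be strictly increasing.
    """

    depth: np.ndarray
    wavelength: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.depth), len(self.wavelength)):
            raise ValueError("reflectance shape must be (n_depth, n_wavelength)")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.reflectance < 0):
            raise ValueError("negative reflectance")

    @classmethod
    def from_csv(cls, path) -> "SpectralCube":
        """Wide CSV: first column depth_cm, remaining columns numeric
        wavelengths in nm."""
        df = pd.read_csv(path, comment="#")
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(depth=df.iloc[:, 0].to_numpy(), wavelength=wl,
                   reflectance=df.iloc[:, 1:].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.reflectance,
                           columns=[f"{w:g}" for w in self.wavelength])
        out.insert(0, "depth_cm", self.depth)
        return out


def _nearest_index(grid: np.ndarray, value: float) -> int:
    i = int(np.argmin(np.abs(grid - value)))
    if abs(grid[i] - value) > 0.51 * np.max(np.diff(grid)):
        raise ValueError(f"wavelength {value} nm not covered by grid")
    return i


def rabd_index(wavelength, reflectance, left_nm: float = 590.0,
               right_nm: float = 730.0,
               trough: tuple[float, float] = (655.0, 680.0)) -> float:
    """Relative absorption band depth of one spectrum.

    The trough minimum is the gridpoint of minimum reflectance within
    ``trough``.  With X bands between the minimum and the right shoulder
    and Y bands between the left shoulder and the minimum, the continuum
    at the minimum is ``(X * R_left + Y * R_right) / (X + Y)`` — linear
    interpolation of the shoulder reflectances on a uniform grid — and
    the index is continuum / R(minimum).
    """
    wl = np.asarray(wavelength, dtype=float)
    r = np.asarray(reflectance, dtype=float)
    if wl.shape != r.shape:
        raise ValueError("wavelength and reflectance must have equal length")
    i_left = _nearest_index(wl, left_nm)
    i_right = _nearest_index(wl, right_nm)
    if not (wl[i_left] <= trough[0] and trough[1] <= wl[i_right]):
        raise ValueError("trough window must lie between the shoulders")
    in_trough = (wl >= trough[0]) & (wl <= trough[1])
    if not np.any(in_trough):
        raise ValueError("no gridpoints inside the trough window")
    trough_idx = np.flatnonzero(in_trough)
    i_min = trough_idx[int(np.argmin(r[trough_idx]))]
    r_min = r[i_min]
    if r_min <= 0:
        raise ValueError("non-positive reflectance at the trough minimum")
    x = i_right - i_min
    y = i_min - i_left
    continuum = (x * r[i_left] + y * r[i_right]) / (x + y)
    return float(continuum / r_min)


def rabd_series(cube: SpectralCube, left_nm: float = 590.0,
                right_nm: float = 730.0,
                trough: tuple[float, float] = (655.0, 680.0),
                smooth_k: int | None = 13) -> pd.DataFrame:
    """RABD index for every scan row of a cube.

    Returns a frame with columns ``depth_cm``, ``rabd`` and (when
    ``smooth_k`` is set) ``rabd_smoothed``, a centred moving average of
    ``smooth_k`` samples as used for plotting TChl profiles.
    """
    vals = np.array([rabd_index(cube.wavelength, row, left_nm, right_nm,
                                trough) for row in cube.reflectance])
    out = pd.DataFrame({"depth_cm": cube.depth, "rabd": vals})
    if smooth_k is not None and smooth_k <= len(vals):
        out["rabd_smoothed"] = moving_average(vals, smooth_k)
    return out


def moving_average(series, k: int = 13) -> np.ndarray:
    """Centred moving average with shrinking windows at the series ends.

    At position i the window is ``[i-h, i+h]`` with ``h = (k-1)/2``,
    clipped to the series, so end values average over the part of the
    window that exists (e.g. [1, 2, 3] with k=3 gives [1.5, 2, 2.5]).
    """
    x = np.asarray(series, dtype=float)
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd and >= 1")
    if k > len(x):
        raise ValueError("k exceeds series length")
    h = (k - 1) // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        out[i] = x[max(0, i - h): min(n, i + h + 1)].mean()
    return out


def bin_by_depth(depth, values, bin_cm: float) -> pd.DataFrame:
    """Mean of values per half-open depth bin [i*bin, (i+1)*bin).

    Empty bins within the occupied span are kept and flagged NaN.
    Returns columns ``bin_top_cm``, ``bin_mid_cm``, ``mean``, ``n``.
    """
    if bin_cm <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(depth, dtype=float)
    v = np.asarray(values, dtype=float)
    idx = np.floor(d / bin_cm).astype(int)
    lo, hi = idx.min(), idx.max()
    bins = np.arange(lo, hi + 1)
    means = np.full(len(bins), np.nan)
    counts = np.zeros(len(bins), dtype=int)
    for j, b in enumerate(bins):
        sel = idx == b
        counts[j] = sel.sum()
        if counts[j]:
            means[j] = v[sel].mean()
    return pd.DataFrame({
        "bin_top_cm": bins * bin_cm,
        "bin_mid_cm": (bins + 0.5) * bin_cm,
        "mean": means,
        "n": counts,
    })
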