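"""Spectrum reading, noise estimation and S/N-thresholded peak picking."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _mzml
from .defaults import MZ_WINDOW, SN_THRESHOLD

__all__ = [
    "Spectrum",
    "Peak",
    "read_spectrum",
    "estimate_noise",
    "pick_peaks",
    "write_peaks_tsv",
]


@dataclass
class Spectrum:
    """A profile spectrum on an ascending m/z axis, restricted to a window."""

    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] = MZ_WINDOW

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) < 2:
            raise ValueError("spectrum needs at least 2 points")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Peak:
    """A picked peak: apex position/height above baseline, S/N and
    intensity relative to the base peak of the same pick run."""

    mz: float
    intensity: float
    sn: float
    relative_intensity: float = 1.0


def _canonicalize(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and merge duplicate m/z values by summing intensity."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if len(uniq) != len(mz):
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, intensity)
        return uniq, summed
    return mz, intensity


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    window: tuple[float, float] = MZ_WINDOW,
) -> Spectrum:
    """Read a spectrum from mzML or two-column text.

    ``format`` is ``"mzml"`` or ``"xy_text"``; if omitted it is inferred
    from the file extension.  Text files hold one ``m/z intensity`` pair
    per line, whitespace- or comma-delimited; ``#`` starts a comment.
    Multi-scan mzML files are averaged: every scan is interpolated onto
    the m/z grid of the first scan and the arithmetic mean is taken.
    Points outside the half-open window ``[low, high)`` are discarded.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy_text"
    if format == "mzml":
        scans = _mzml.read_mzml(path)
        grid = scans[0][0]
        stack = [np.interp(grid, mz, inten) for mz, inten in scans]
        mz, intensity = grid.copy(), np.mean(stack, axis=0)
    elif format == "xy_text":
        mzs, intens = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
        mz, intensity = np.asarray(mzs), np.asarray(intens)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")

    mz, intensity = _canonicalize(mz, intensity)
    low, high = window
    keep = (mz >= low) & (mz < high)
    mz, intensity = mz[keep], intensity[keep]
    if len(mz) < 2:
        raise ValueError(f"{path}: fewer than 2 points inside window {window}")
    return Spectrum(mz=mz, intensity=np.clip(intensity, 0.0, None), window=window)


def _block_median_baseline(intensity: np.ndarray, window: int) -> np.ndarray:
    """Piecewise baseline: medians of consecutive blocks, linearly
    interpolated back onto the full axis.  O(n), robust to sparse peaks."""
    n = len(intensity)
    window = max(3, min(window, n))
    n_blocks = max(1, n // window)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    meds = np.array(
        [np.median(intensity[a:b]) for a, b in zip(edges[:-1], edges[1:])]
    )
    if n_blocks == 1:
        return np.full(n, meds[0])
    return np.interp(np.arange(n), centers, meds)


def estimate_noise(spectrum: Spectrum, baseline_window: int = 201) -> float:
    """Robust noise scale: 1.4826 x MAD of baseline-subtracted intensities.

    The baseline is a rolling (block) median, so isolated peaks do not
    inflate the estimate.  Returns 0 for a flat spectrum (and, more
    generally, whenever the majority of residuals are exactly zero, as in
    a noiseless simulation).
    """
    if len(spectrum) < 16:
        raise ValueError("need at least 16 points to estimate noise")
    resid = spectrum.intensity - _block_median_baseline(
        spectrum.intensity, baseline_window
    )
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def pick_peaks(
    spectrum: Spectrum,
    sn_threshold: float = SN_THRESHOLD,
    baseline_window: int = 201,
    min_shape_frac: float = 0.4,
) -> list[Peak]:
    """Local maxima above baseline with S/N >= ``sn_threshold``.

    S/N is apex height above the rolling-median baseline divided by the
    MAD-based noise scale (infinite when the noise estimate is 0); peaks
    with S/N >= the threshold are kept.  Two shape criteria reject noise
    artefacts: the peak prominence must also reach ``sn_threshold`` times
    the noise (drops noise bumps riding on the flank of a larger peak) and
    both immediate neighbours must carry at least ``min_shape_frac`` of
    the apex height (drops single-sample spikes).  Apex m/z and height are
    refined by 3-point parabolic interpolation in log space (exact for a
    noiseless Gaussian).  ``relative_intensity`` is expressed against the
    tallest returned peak.
    """
    from scipy.signal import find_peaks

    noise = estimate_noise(spectrum, baseline_window)
    resid = spectrum.intensity - _block_median_baseline(
        spectrum.intensity, baseline_window
    )
    mz = spectrum.mz

    floor = sn_threshold * noise if noise > 0 else np.max(resid) * 1e-9
    if floor <= 0:
        return []
    idx, _ = find_peaks(resid, height=floor, prominence=floor)

    # merge unresolved twin maxima: if the valley between two adjacent
    # candidates stays above half the smaller apex the pair is one peak
    # split by noise — keep the taller candidate
    merged: list[int] = []
    for i in idx:
        if merged:
            j = merged[-1]
            valley = resid[j : i + 1].min()
            if valley > 0.5 * min(resid[i], resid[j]):
                if resid[i] > resid[j]:
                    merged[-1] = i
                continue
        merged.append(i)

    peaks: list[Peak] = []
    for i in merged:
        h = resid[i]
        sn = math.inf if noise == 0 else h / noise
        if sn < sn_threshold:
            continue
        if resid[i - 1] < min_shape_frac * h or resid[i + 1] < min_shape_frac * h:
            continue
        # 5-point support: a resolved peak keeps >= 10% of its apex two
        # samples out; runs of 2-3 elevated noise samples do not
        lo2, hi2 = max(i - 2, 0), min(i + 2, len(resid) - 1)
        if resid[lo2] < 0.1 * min_shape_frac * h or resid[hi2] < 0.1 * min_shape_frac * h:
            continue
        apex_mz, apex_h = _refine_apex(mz[i - 1 : i + 2], resid[i - 1 : i + 2])
        peaks.append(Peak(mz=apex_mz, intensity=apex_h, sn=sn))

    if peaks:
        base = max(p.intensity for p in peaks)
        for p in peaks:
            p.relative_intensity = p.intensity / base
    return peaks


def _refine_apex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through 3 points of log-intensity."""
    if np.any(y <= 0):
        # plain parabola fallback when log is undefined
        coeffs = np.polyfit(x, y, 2)
        if coeffs[0] >= 0:
            return float(x[1]), float(y[1])
        xv = -coeffs[1] / (2 * coeffs[0])
        return float(xv), float(np.polyval(coeffs, xv))
    coeffs = np.polyfit(x, np.log(y), 2)
    if coeffs[0] >= 0:
        return float(x[1]), float(y[1])
    xv = -coeffs[1] / (2 * coeffs[0])
    if not (x[0] <= xv <= x[2]):
        return float(x[1]), float(y[1])
    return float(xv), float(np.exp(np.polyval(coeffs, xv)))


def write_peaks_tsv(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\tsn\trelative_intensity\n")
        for p in peaks:
            fh.write(f"{p.mz:.4f}\t{p.intensity:.4f}\t{p.sn:.3f}\t{p.relative_intensity:.4f}\n")
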