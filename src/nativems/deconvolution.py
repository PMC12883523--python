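"""Charge-state series detection and neutral-mass estimation.

Mirrors the manual procedure used with electrospray data: adjacent peaks of
one species differ by one charge, so their spacing fixes the charge, and
each peak then independently reports the neutral mass M = z*(mz - m_proton).
A series is accepted when several peaks agree on one mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .defaults import PROTON_MASS
from .spectrum_io import Peak

__all__ = [
    "DeconvParams",
    "ChargeSeries",
    "mz_from_mass",
    "mass_from_mz",
    "infer_charge_from_adjacent",
    "find_series",
    "estimate_mass",
    "write_series_tsv",
]


@dataclass
class DeconvParams:
    proton_mass: float = PROTON_MASS
    z_range: tuple[int, int] = (5, 40)
    min_series_length: int = 3
    consistency_tol: float = 5e-4  # relative; stricter than assignment
    allow_shared_peaks: bool = False
    #: maximum deviation of the unrounded charge estimate from an integer
    charge_round_tol: float = 0.15
    weight_by_intensity: bool = False

    def __post_init__(self) -> None:
        if self.z_range[0] < 1:
            raise ValueError("z_min must be >= 1")
        if self.min_series_length < 1:
            raise ValueError("min_series_length must be >= 1")
        if self.consistency_tol <= 0:
            raise ValueError("consistency_tol must be > 0")


@dataclass
class ChargeSeries:
    """Peaks assigned consecutive charges, with the implied neutral mass."""

    assignments: list[tuple[Peak, int]]
    neutral_mass: float = 0.0
    mass_spread: float = 0.0
    summed_intensity: float = 0.0
    relative_intensity: float = 1.0
    degenerate: bool = False

    @property
    def charges(self) -> list[int]:
        return sorted(z for _, z in self.assignments)


def mz_from_mass(mass: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of a species of neutral mass ``mass`` carrying ``z`` protons."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * proton_mass) / z


def mass_from_mz(mz: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """Neutral mass implied by one peak at ``mz`` with charge ``z``."""
    if mz <= 0:
        raise ValueError("mz must be > 0")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return z * (mz - proton_mass)


def infer_charge_from_adjacent(
    mz_high: float, mz_low: float, params: DeconvParams | None = None
) -> int | None:
    """Charge of the higher-m/z peak, assuming consecutive charge states.

    If the peaks belong to one species at charges z (high m/z) and z+1
    (low m/z), then (mz_low - m_proton)/(mz_high - mz_low) equals z
    exactly.  Returns ``None`` when the unrounded estimate is more than
    ``charge_round_tol`` from an integer or the integer is outside
    ``z_range`` — absence is a valid outcome for unrelated peaks.
    """
    params = params or DeconvParams()
    if mz_high <= mz_low:
        raise ValueError("mz_high must exceed mz_low")
    raw = (mz_low - params.proton_mass) / (mz_high - mz_low)
    z = round(raw)
    if abs(raw - z) > params.charge_round_tol:
        return None
    if not (params.z_range[0] <= z <= params.z_range[1]):
        return None
    return int(z)


def _grow_ladder(
    seed_peak_idx: int,
    seed_z: int,
    mzs: np.ndarray,
    params: DeconvParams,
) -> list[tuple[int, int]] | None:
    """Extend a (peak, charge) hypothesis across the charge range.

    Walks charges outward from the seed, predicting each next m/z from the
    running mean mass and accepting the nearest peak whose implied mass
    agrees within ``consistency_tol``; at most one missing charge (gap) is
    tolerated per direction before the walk stops.
    """
    proton = params.proton_mass
    mass0 = seed_z * (mzs[seed_peak_idx] - proton)
    if mass0 <= 0:
        return None
    members = {seed_z: seed_peak_idx}
    masses = [mass0]

    for direction in (+1, -1):
        gap = 0
        z = seed_z
        while gap <= 1:
            z += direction
            if not (params.z_range[0] <= z <= params.z_range[1]):
                break
            mean = float(np.mean(masses))
            predicted = (mean + z * proton) / z
            j = int(np.searchsorted(mzs, predicted))
            best, best_err = None, None
            for cand in (j - 1, j):
                if 0 <= cand < len(mzs) and cand not in members.values():
                    implied = z * (mzs[cand] - proton)
                    err = abs(implied - mean)
                    if err <= params.consistency_tol * mean and (
                        best_err is None or err < best_err
                    ):
                        best, best_err = cand, err
            if best is None:
                gap += 1
                continue
            members[z] = best
            masses.append(z * (mzs[best] - proton))
    if len(members) < max(2, params.min_series_length):
        return None
    return sorted(members.items())  # list of (z, peak index)


def find_series(
    peaks: Sequence[Peak], params: DeconvParams | None = None
) -> list[ChargeSeries]:
    """Group picked peaks into mutually consistent charge-state ladders.

    Every adjacent-looking peak pair seeds a charge hypothesis via
    :func:`infer_charge_from_adjacent`; each hypothesis is grown into a
    ladder, and ladders are then accepted greedily by summed intensity
    (ties: longer ladder, then lower neutral mass).  Unless
    ``allow_shared_peaks`` is set, a peak joins at most one series.
    """
    params = params or DeconvParams()
    if len(peaks) < params.min_series_length:
        return []
    order = np.argsort([p.mz for p in peaks])
    sorted_peaks = [peaks[i] for i in order]
    mzs = np.array([p.mz for p in sorted_peaks])
    intens = np.array([p.intensity for p in sorted_peaks])

    # candidate ladders from every plausible adjacent pair
    candidates: dict[tuple, list[tuple[int, int]]] = {}
    for i in range(len(mzs)):
        # pair peak i (low m/z, charge z+1) with a higher-m/z peak
        for j in range(i + 1, len(mzs)):
            z = infer_charge_from_adjacent(mzs[j], mzs[i], params)
            if z is None:
                # spacing grows with separation; stop once even z_min fails
                if (mzs[i] - params.proton_mass) / (mzs[j] - mzs[i]) < params.z_range[0] - 1:
                    break
                continue
            ladder = _grow_ladder(j, z, mzs, params)
            if ladder is not None and len(ladder) >= params.min_series_length:
                key = tuple(ladder)
                candidates.setdefault(key, list(ladder))

    proton = params.proton_mass

    def ranking(ladder: list[tuple[int, int]]):
        total = sum(intens[idx] for _, idx in ladder)
        mean_mass = float(np.mean([z * (mzs[idx] - proton) for z, idx in ladder]))
        return (-total, -len(ladder), mean_mass)

    claimed: set[int] = set()
    series_list: list[ChargeSeries] = []
    for ladder in sorted(candidates.values(), key=ranking):
        if not params.allow_shared_peaks:
            ladder = [(z, idx) for z, idx in ladder if idx not in claimed]
            if len(ladder) < params.min_series_length:
                continue
            zs = [z for z, _ in ladder]
            if max(np.diff(zs), default=0) > 2:  # trimming broke the ladder
                continue
        series = ChargeSeries(
            assignments=[(sorted_peaks[idx], z) for z, idx in ladder]
        )
        estimate_mass(series, params)
        if not params.allow_shared_peaks:
            claimed.update(idx for _, idx in ladder)
        series_list.append(series)

    if series_list:
        top = max(s.summed_intensity for s in series_list)
        for s in series_list:
            s.relative_intensity = s.summed_intensity / top
        series_list.sort(key=lambda s: -s.summed_intensity)
    return series_list


def estimate_mass(
    series: ChargeSeries, params: DeconvParams | None = None
) -> tuple[float, float]:
    """Neutral mass and spread from the per-peak masses of one series.

    Each assigned peak yields M_i = z_i*(mz_i - m_proton); the series mass
    is their unweighted mean by default (intensity-weighted if configured)
    and the spread is the sample standard deviation.  Both are written
    back onto the series.  A single-peak series is flagged degenerate.
    """
    params = params or DeconvParams()
    masses = np.array(
        [mass_from_mz(p.mz, z, params.proton_mass) for p, z in series.assignments]
    )
    weights = (
        np.array([p.intensity for p, _ in series.assignments])
        if params.weight_by_intensity
        else None
    )
    mean = float(np.average(masses, weights=weights))
    spread = float(np.std(masses, ddof=1)) if len(masses) > 1 else 0.0
    series.neutral_mass = mean
    series.mass_spread = spread
    series.summed_intensity = float(sum(p.intensity for p, _ in series.assignments))
    series.degenerate = len(masses) < 2
    return mean, spread


def write_series_tsv(series_list: Sequence[ChargeSeries], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "series\tneutral_mass\tmass_spread\tcharges\tn_peaks\t"
            "summed_intensity\trelative_intensity\n"
        )
        for i, s in enumerate(series_list, start=1):
            charges = ",".join(str(z) for z in s.charges)
            fh.write(
                f"{i}\t{s.neutral_mass:.3f}\t{s.mass_spread:.3f}\t{charges}\t"
                f"{len(s.assignments)}\t{s.summed_intensity:.3f}\t"
                f"{s.relative_intensity:.4f}\n"
            )
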