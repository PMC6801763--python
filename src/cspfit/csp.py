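"""Weighted chemical-shift perturbations and exchange-regime calls.

The per-residue binding readout is the combined amide shift distance

    dd_w = sqrt( ddH^2 + (alpha * ddN)^2 ),

with 15N changes scaled by ``alpha`` so one ppm of nitrogen perturbation
counts in proportion to the nuclei's gyromagnetic ratios
(|gamma(15N)/gamma(1H)| ~= 0.1014 by default; the 0.14/0.154 conventions are
one argument away).  Each residue's trajectory is measured against the free
(zero-ligand) reference spectrum; residues whose peaks vanish at some points
(intermediate exchange) keep explicit gaps, never imputed values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .peaks import TitrationSeries

__all__ = [
    "GYRO_RATIO_N15",
    "CSPProfile",
    "ExchangeCall",
    "weighted_csp",
    "build_profiles",
    "classify_exchange",
    "classify_series",
]

#: |gamma(15N) / gamma(1H)|
GYRO_RATIO_N15 = 0.1014

#: shift distances below this (ppm) are treated as no perturbation
UNPERTURBED_FLOOR = 0.005

#: peaks below this fraction of their free-state height count as broadened
BROADENING_THETA = 0.3


@dataclass
class CSPProfile:
    """Weighted shift distance of one residue across the titration.

    ``delta_delta[i]`` is dd_w at point i (NaN where the peak is missing);
    ``flags[i]`` is ``"observed"`` or ``"missing"``.  Point 0 is the free
    reference and is exactly 0.
    """

    residue_id: int
    delta_delta: np.ndarray
    flags: tuple[str, ...]

    @property
    def observed(self) -> np.ndarray:
        return np.array([f == "observed" for f in self.flags])


@dataclass(frozen=True)
class ExchangeCall:
    residue_id: int
    regime: str  # "fast" | "intermediate" | "unperturbed"
    evidence: str


def weighted_csp(dh_free: float, dn_free: float, dh_i: float, dn_i: float,
                 alpha: float = GYRO_RATIO_N15) -> float:
    """Gyromagnetic-ratio-weighted shift distance between two peak positions."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return math.hypot(dh_i - dh_free, alpha * (dn_i - dn_free))


def build_profiles(series: TitrationSeries,
                   alpha: float = GYRO_RATIO_N15) -> list[CSPProfile]:
    """One :class:`CSPProfile` per residue of the free reference spectrum.

    Residues appearing only at later points have no reference and are skipped
    with a warning; absences at later points are flagged missing.
    """
    free = series.points[0].peaks
    later = set().union(*(set(p.peaks) for p in series.points[1:])) if len(series.points) > 1 else set()
    orphans = later - set(free)
    if orphans:
        warnings.warn(
            f"residues {sorted(orphans)} absent from the free reference; skipped",
            stacklevel=2)
    profiles = []
    for rid in series.residues:
        ref = free[rid]
        dd = np.empty(len(series.points))
        flags = []
        for i, point in enumerate(series.points):
            pk = point.peaks.get(rid)
            if pk is None:
                dd[i] = np.nan
                flags.append("missing")
            elif i == 0:
                dd[i] = 0.0  # reference point: zero by construction
                flags.append("observed")
            else:
                dd[i] = weighted_csp(ref.delta_h, ref.delta_n,
                                     pk.delta_h, pk.delta_n, alpha)
                flags.append("observed")
        profiles.append(CSPProfile(residue_id=rid, delta_delta=dd,
                                   flags=tuple(flags)))
    return profiles


def classify_exchange(profile: CSPProfile,
                      heights=None,
                      theta: float = BROADENING_THETA,
                      epsilon: float = UNPERTURBED_FLOOR) -> ExchangeCall:
    """Call the exchange regime of one residue.

    ``intermediate`` if any nonzero-ligand point is missing, or (when
    ``heights`` are supplied, one per point) broadened below ``theta`` times
    the free-state height; ``unperturbed`` if every observed dd_w is below
    ``epsilon``; otherwise ``fast``.  Intermediate-exchange residues must not
    enter quantitative fits — their peak positions are biased.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    missing = [i for i, f in enumerate(profile.flags) if f == "missing" and i > 0]
    if missing:
        return ExchangeCall(profile.residue_id, "intermediate",
                            f"peak absent at points {_runs(missing)}")
    if heights is not None and heights[0] is not None and heights[0] > 0:
        broadened = [i for i, h in enumerate(heights)
                     if i > 0 and h is not None and h < theta * heights[0]]
        if broadened:
            return ExchangeCall(profile.residue_id, "intermediate",
                                f"peak broadened below {theta:g} of free height "
                                f"at points {_runs(broadened)}")
    obs = profile.delta_delta[profile.observed]
    if np.all(obs < epsilon):
        return ExchangeCall(profile.residue_id, "unperturbed",
                            f"max shift distance {obs.max():.4g} ppm < {epsilon:g} ppm")
    return ExchangeCall(profile.residue_id, "fast",
                        f"all points observed, max shift distance {obs.max():.4g} ppm")


def classify_series(series: TitrationSeries, profiles,
                    theta: float = BROADENING_THETA,
                    epsilon: float = UNPERTURBED_FLOOR) -> list[ExchangeCall]:
    """Classify every profile, pulling per-point peak heights from the series."""
    return [classify_exchange(p, heights=series.heights(p.residue_id),
                              theta=theta, epsilon=epsilon)
            for p in profiles]


def _runs(indices: list[int]) -> str:
    """Compact '3-5, 8' rendering of sorted point indices."""
    parts, start, prev = [], indices[0], indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = i
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ", ".join(parts)
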