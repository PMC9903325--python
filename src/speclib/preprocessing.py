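"""Spectrum preprocessing: unspecific-ion removal, windowed peak picking,
intensity normalization.

Input and library spectra are run through the same pipeline so their peak
counts (N_I, N_L) and intensity ranks are directly comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .constants import AMMONIA, PROTON, WATER
from .domain import Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing pipeline.

    depth
        Peak picking depth m: maximum peaks kept per fixed 100 Th window.
    low_mass_cutoff
        Peaks below this m/z (Th) are removed (immonium / small-ion region).
    precursor_window
        Half-width (Th) of the exclusion zone around each precursor-derived
        species (charge-reduced ladder and its -H2O/-NH3 satellites).
    normalization_total
        Target sum of intensities after scaling; only ratios matter
        downstream.
    fragment_tol_ppm
        Fragment match tolerance carried along for signature purposes.
    """

    depth: int = 15
    low_mass_cutoff: float = 145.0
    precursor_window: float = 2.0
    normalization_total: float = 100.0
    fragment_tol_ppm: float = 20.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("peak picking depth must be >= 1")
        if self.low_mass_cutoff < 0 or self.precursor_window < 0:
            raise ValueError("cutoffs must be non-negative")
        if self.normalization_total <= 0:
            raise ValueError("normalization_total must be positive")


def precursor_exclusion_centers(precursor_mz: float, charge: int) -> list[float]:
    """m/z of the precursor, its charge-reduced species at z, z-1, .., 1,
    and their water/ammonia neutral-loss satellites."""
    neutral = precursor_mz * charge - charge * PROTON
    centers = []
    for z in range(charge, 0, -1):
        base = (neutral + z * PROTON) / z
        centers.extend([base, base - WATER / z, base - AMMONIA / z])
    return centers


def remove_unspecific_peaks(s: Spectrum, params: PreprocessParams) -> Spectrum:
    """Drop low-mass ions and all precursor-derived species.

    A spectrum emptied entirely is returned flagged-empty so the search can
    skip it.
    """
    centers = precursor_exclusion_centers(s.precursor_mz, s.precursor_charge)
    kept = []
    for peak in s.peaks:
        if peak.mz < params.low_mass_cutoff:
            continue
        if any(abs(peak.mz - c) <= params.precursor_window for c in centers):
            continue
        kept.append(replace(peak))
    out = s.copy()
    out.peaks = kept
    if not kept:
        logger.warning("spectrum %s emptied by unspecific-ion removal", s.identifier)
        out.flagged_empty = True
    return out


def pick_peaks(s: Spectrum, depth: int) -> Spectrum:
    """Keep at most ``depth`` peaks per fixed window [100k, 100(k+1)) Th.

    Within a window the highest-intensity peaks survive; intensity ties are
    broken by keeping the lower m/z peak (deterministic, seed-free).
    """
    windows: dict[int, list[int]] = {}
    for i, peak in enumerate(s.peaks):
        windows.setdefault(int(peak.mz // 100.0), []).append(i)
    keep: set[int] = set()
    for indices in windows.values():
        if len(indices) <= depth:
            keep.update(indices)
        else:
            best = sorted(indices, key=lambda i: (-s.peaks[i].intensity, s.peaks[i].mz))
            keep.update(best[:depth])
    out = s.copy()
    out.peaks = [replace(p) for i, p in enumerate(s.peaks) if i in keep]
    return out


def normalize_intensities(s: Spectrum, total: float = 100.0) -> Spectrum:
    """Scale intensities so their sum equals ``total``; ranks unchanged."""
    current = math.fsum(p.intensity for p in s.peaks)
    if current <= 0:
        raise ValueError(f"spectrum {s.identifier}: all intensities zero")
    scale = total / current
    out = s.copy()
    for peak in out.peaks:
        peak.intensity *= scale
    out.normalized = True
    return out


def preprocess(s: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Full pipeline: unspecific-ion removal, peak picking, normalization.

    Idempotent: a preprocessed spectrum passes through unchanged (up to
    floating-point rescaling noise).
    """
    params = params or PreprocessParams()
    out = remove_unspecific_peaks(s, params)
    if out.flagged_empty:
        return out
    out = pick_peaks(out, params.depth)
    return normalize_intensities(out, params.normalization_total)
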