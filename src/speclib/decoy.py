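"""Decoy spectral library generation by shuffle-and-reposition.

A decoy spectrum is built from an annotated target spectrum in two steps:
the peptide's interior residues are shuffled (termini fixed, positioned
modifications travelling with their residues) until the positional
Kendall-Tau correlation with the identity drops to tau <= 0.5; then every
annotated peak is moved by the theoretical mass shift delta of its ion
between target and decoy sequence, keeping its intensity. Peaks that would
leave the detectable m/z range are discarded; unannotated peaks are copied
verbatim. The result is realistic — same peak count (minus out-of-range
losses), intensities and precursor mass — but wrong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation import annotate_spectrum, annotation_signature, BASE_SERIES
from .domain import (
    IonAnnotation,
    LibraryEntry,
    Modification,
    Peak,
    Peptide,
    Spectrum,
    fragment_mz,
)

logger = logging.getLogger(__name__)

TAU_THRESHOLD = 0.5


@dataclass
class ShuffleResult:
    """Outcome of a successful decoy shuffle.

    ``permutation[i]`` is the new position of the residue originally at
    index i; residue *instances* are tracked so tau is well defined even
    for repeated amino acids.
    """

    decoy_peptide: Peptide
    permutation: list[int]
    tau: float
    attempts: int


def positional_tau(permutation: Sequence[int]) -> float:
    """Kendall-Tau rank correlation between the identity and a permutation
    of 0..L-1: tau = 1 - 4q / (L(L-1)) with q the inversion count."""
    L = len(permutation)
    if L < 2:
        raise ValueError("permutation must have length >= 2")
    q = 0
    for i in range(L):
        for j in range(i + 1, L):
            if permutation[i] > permutation[j]:
                q += 1
    return 1.0 - 4.0 * q / (L * (L - 1))


def shuffle_decoy_sequence(
    peptide: Peptide, rng: np.random.Generator
) -> Optional[ShuffleResult]:
    """Shuffle interior residues keeping both termini fixed.

    Accepts the first permutation with tau <= 0.5; retries up to
    len(sequence)^2 times and returns None on exhaustion (or for sequences
    too short to shuffle, length < 4).
    """
    seq = peptide.sequence
    L = len(seq)
    if L < 4:
        logger.info("sequence %s too short for decoy shuffling", seq)
        return None
    interior = list(range(1, L - 1))
    max_attempts = L * L
    for attempt in range(1, max_attempts + 1):
        shuffled = list(rng.permutation(interior))
        # residue originally at interior[k] moves to position 1 + index of
        # interior[k] in the shuffled order
        permutation = list(range(L))
        for new_pos, orig_idx in enumerate(shuffled, start=1):
            permutation[orig_idx] = new_pos
        tau = positional_tau(permutation)
        if tau <= TAU_THRESHOLD:
            decoy_seq = [""] * L
            for orig_idx, new_pos in enumerate(permutation):
                decoy_seq[new_pos] = seq[orig_idx]
            mods = [
                Modification(
                    permutation[m.position]
                    if isinstance(m.position, int)
                    else m.position,
                    m.mass_delta,
                    m.name,
                )
                for m in peptide.modifications
            ]
            return ShuffleResult(
                decoy_peptide=Peptide("".join(decoy_seq), mods, peptide.charge),
                permutation=permutation,
                tau=tau,
                attempts=attempt,
            )
    logger.warning(
        "no decoy for %s after %d shuffle attempts", seq, max_attempts
    )
    return None


def _ion_delta(
    ann: IonAnnotation, target: Peptide, decoy: Peptide
) -> Optional[float]:
    """m/z shift of an annotated ion between target and decoy sequence, at
    the annotation's charge; None for ions without a residue span."""
    if ann.series in ("precursor_derived", "immonium"):
        return None
    return fragment_mz(decoy, ann) - fragment_mz(target, ann)


def build_decoy_spectrum(
    entry: LibraryEntry,
    shuffle: ShuffleResult,
    detectable_range: Optional[tuple[float, float]] = None,
) -> LibraryEntry:
    """Reposition annotated peaks of an annotated target entry by their
    per-ion delta; drop peaks shifted outside the detectable range; copy
    unannotated peaks as is. Intensities are preserved."""
    target = entry.peptide
    decoy = shuffle.decoy_peptide
    spectrum = entry.spectrum
    if detectable_range is None:
        detectable_range = (spectrum.peaks[0].mz, spectrum.peaks[-1].mz)
    lo, hi = detectable_range
    peaks: list[Peak] = []
    dropped = 0
    for peak in spectrum.peaks:
        if peak.annotation is None:
            peaks.append(Peak(peak.mz, peak.intensity))
            continue
        delta = _ion_delta(peak.annotation, target, decoy)
        if delta is None:
            peaks.append(Peak(peak.mz, peak.intensity, peak.annotation))
            continue
        new_mz = peak.mz + delta
        if not lo <= new_mz <= hi:
            dropped += 1
            continue
        peaks.append(Peak(new_mz, peak.intensity, peak.annotation))
    if dropped:
        logger.debug("decoy of %s dropped %d out-of-range peaks", target.sequence, dropped)
    decoy_spectrum = Spectrum(
        identifier=f"DECOY_{spectrum.identifier}",
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        peaks=peaks,
    )
    return LibraryEntry(
        peptide=decoy,
        spectrum=decoy_spectrum,
        is_decoy=True,
        origin=entry.origin,
        comment_tokens=dict(entry.comment_tokens),
    )


def is_annotated(entry: LibraryEntry) -> bool:
    return any(p.annotation is not None for p in entry.spectrum.peaks)


def generate_decoy_library(
    entries: Sequence[LibraryEntry],
    tol_ppm: float = 20.0,
    seed: int = 0,
    detectable_range: Optional[tuple[float, float]] = None,
    depth: int = 15,
) -> list[LibraryEntry]:
    """One decoy per target entry where shuffling succeeds.

    Unannotated entries are annotated at ``tol_ppm`` first (the annotation
    tolerance must match the search fragment tolerance). Per-entry rng
    streams derive from (seed, entry index), so output is order-stable and
    reproducible: the same seed yields a byte-identical decoy MSP.
    """
    signature = annotation_signature(tol_ppm, BASE_SERIES, depth)
    decoys: list[LibraryEntry] = []
    failures = 0
    for index, entry in enumerate(entries):
        if not is_annotated(entry):
            entry = annotate_spectrum(entry, tol_ppm)
        rng = np.random.default_rng([seed, index])
        shuffle = shuffle_decoy_sequence(entry.peptide, rng)
        if shuffle is None:
            failures += 1
            continue
        decoy = build_decoy_spectrum(entry, shuffle, detectable_range)
        decoy.comment_tokens["AnnotSig"] = signature
        decoys.append(decoy)
    if failures:
        logger.info("%d/%d entries produced no decoy", failures, len(entries))
    return decoys
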