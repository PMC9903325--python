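"""Iterative fragment-ion annotation of library spectra.

The annotator starts from the specific backbone series (b/y), matches them
to peaks, then uses each confirmed match to propose derived ions — neutral
losses gated on the residues the fragment spans, and internal fragments
from a second backbone cleavage — repeating until a fixpoint. When two
annotations compete for a peak, a fixed priority table lets the more common
ion type win; remaining ties go to the smaller mass error.

High annotation coverage is what makes shuffle-and-reposition decoys
possible: only annotated peaks can be repositioned.
"""

from __future__ import annotations

import bisect
import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .constants import AMMONIA, H2O_LOSS_RESIDUES, NH3_LOSS_RESIDUES, WATER
from .domain import IonAnnotation, LibraryEntry, Peptide, fragment_mz, ppm_error

logger = logging.getLogger(__name__)

#: Priority table, lower = more common = wins conflicts (HCD ordering).
DEFAULT_PRIORITY: dict[str, int] = {
    "y": 0,
    "b": 1,
    "y_loss": 2,
    "b_loss": 3,
    "a": 4,
    "a_loss": 5,
    "internal": 6,
    "immonium": 7,
    "precursor_derived": 8,
}

#: Base series proposed before any peak is matched.
BASE_SERIES = ("b", "y")

#: Minimum residue count of an internal fragment.
MIN_INTERNAL_LENGTH = 2


@dataclass(frozen=True)
class TheoreticalIon:
    """A proposed fragment ion: its annotation, theoretical m/z, the
    iteration that produced it (0 = base series) and its priority."""

    annotation: IonAnnotation
    mz: float
    generation: int
    priority: int


def _make_ion(
    peptide: Peptide,
    ann: IonAnnotation,
    generation: int,
    priority: dict[str, int],
) -> TheoreticalIon:
    return TheoreticalIon(
        annotation=ann,
        mz=fragment_mz(peptide, ann),
        generation=generation,
        priority=priority[ann.series],
    )


def theoretical_fragments(
    peptide: Peptide,
    series: Iterable[str] = BASE_SERIES,
    max_charge: int = 1,
    priority: Optional[dict[str, int]] = None,
    generation: int = 0,
) -> list[TheoreticalIon]:
    """Backbone fragment ions (b/y, optionally a) for ordinals 1..len-1 at
    charges 1..max_charge, modification masses included, sorted by m/z."""
    if len(peptide.sequence) < 2:
        raise ValueError("peptide shorter than 2 residues has no fragments")
    priority = priority or DEFAULT_PRIORITY
    ions = []
    for ser in series:
        for ordinal in range(1, len(peptide.sequence)):
            for charge in range(1, max_charge + 1):
                ann = IonAnnotation(series=ser, ordinal=ordinal, charge=charge)
                ions.append(_make_ion(peptide, ann, generation, priority))
    ions.sort(key=lambda ion: ion.mz)
    return ions


def _loss_variants(ann: IonAnnotation, peptide: Peptide) -> list[IonAnnotation]:
    if ann.neutral_loss:
        return []
    start, end = ann.span(len(peptide.sequence))
    span = peptide.sequence[start:end]
    variants = []
    if any(aa in H2O_LOSS_RESIDUES for aa in span):
        variants.append(
            IonAnnotation(
                series=("internal" if ann.series == "internal"
                        else f"{ann.base_series}_loss"),
                ordinal=ann.ordinal,
                charge=ann.charge,
                neutral_loss=WATER,
                internal_bounds=ann.internal_bounds,
            )
        )
    if any(aa in NH3_LOSS_RESIDUES for aa in span):
        variants.append(
            IonAnnotation(
                series=("internal" if ann.series == "internal"
                        else f"{ann.base_series}_loss"),
                ordinal=ann.ordinal,
                charge=ann.charge,
                neutral_loss=AMMONIA,
                internal_bounds=ann.internal_bounds,
            )
        )
    return variants


def _internal_fragments(ann: IonAnnotation, peptide: Peptide) -> list[IonAnnotation]:
    """Internal fragments from a second backbone cleavage of a matched b/y
    ion; restricted to length >= 2 and excluding either terminus."""
    length = len(peptide.sequence)
    if ann.series not in ("b", "y"):
        return []
    start, end = ann.span(length)
    out = []
    if ann.series == "b":
        # second cleavage after residue i keeps the C-terminal part [i, end)
        for i in range(1, end - MIN_INTERNAL_LENGTH + 1):
            out.append(
                IonAnnotation(series="internal", internal_bounds=(i, end))
            )
    else:
        # second cleavage keeps the N-terminal part [start, j), j < length
        for j in range(start + MIN_INTERNAL_LENGTH, length):
            out.append(
                IonAnnotation(series="internal", internal_bounds=(start, j))
            )
    return out


def derive_ions(
    matched: Sequence[TheoreticalIon],
    peptide: Peptide,
    priority: Optional[dict[str, int]] = None,
) -> list[TheoreticalIon]:
    """Derived ions from confirmed matches: neutral-loss satellites (gated on
    the spanned residues) and internal fragments of matched b/y ions.

    Never proposes an annotation twice within the returned list.
    """
    priority = priority or DEFAULT_PRIORITY
    seen: set[IonAnnotation] = set()
    derived: list[TheoreticalIon] = []
    for ion in matched:
        generation = ion.generation + 1
        candidates = _loss_variants(ion.annotation, peptide)
        candidates += _internal_fragments(ion.annotation, peptide)
        for ann in candidates:
            if ann in seen:
                continue
            seen.add(ann)
            derived.append(_make_ion(peptide, ann, generation, priority))
    derived.sort(key=lambda ion: ion.mz)
    return derived


def _candidates_for_peak(
    mz: float, ions: list[TheoreticalIon], ion_mzs: list[float], tol_ppm: float
) -> list[TheoreticalIon]:
    half = mz * tol_ppm * 1e-6
    lo = bisect.bisect_left(ion_mzs, mz - half - 1e-9)
    hi = bisect.bisect_right(ion_mzs, mz + half + 1e-9)
    return [
        ion
        for ion in ions[lo:hi]
        if abs(ppm_error(mz, ion.mz)) <= tol_ppm
    ]


def _annotation_sort_key(ann: IonAnnotation):
    return (ann.series, ann.charge, ann.ordinal, ann.internal_bounds or (0, 0),
            ann.neutral_loss)


def annotate_spectrum(
    entry: LibraryEntry,
    tol_ppm: float = 20.0,
    max_charge: Optional[int] = None,
    priority: Optional[dict[str, int]] = None,
) -> LibraryEntry:
    """Annotate an entry's spectrum by the iterative expert system.

    Each peak receives at most one annotation; the loop stops when a pass
    annotates nothing new (bounded by the peak count). Returns an annotated
    copy; the annotated intensity fraction is logged.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    priority = priority or DEFAULT_PRIORITY
    peptide = entry.peptide
    if max_charge is None:
        max_charge = min(2, peptide.charge)
    out = entry.copy()
    peaks = out.spectrum.peaks

    pool = theoretical_fragments(peptide, BASE_SERIES, max_charge, priority)
    proposed: set[IonAnnotation] = {ion.annotation for ion in pool}
    unexpanded: list[TheoreticalIon] = []
    assigned: dict[int, TheoreticalIon] = {}

    while True:
        pool.sort(key=lambda ion: ion.mz)
        pool_mzs = [ion.mz for ion in pool]
        new_matches: list[TheoreticalIon] = []
        for i, peak in enumerate(peaks):
            if i in assigned:
                continue
            cands = _candidates_for_peak(peak.mz, pool, pool_mzs, tol_ppm)
            if not cands:
                continue
            best = min(
                cands,
                key=lambda ion: (
                    ion.priority,
                    abs(ppm_error(peak.mz, ion.mz)),
                    _annotation_sort_key(ion.annotation),
                ),
            )
            assigned[i] = best
            new_matches.append(best)
        if not new_matches:
            break
        unexpanded.extend(new_matches)
        derived = derive_ions(unexpanded, peptide, priority)
        unexpanded = []
        fresh = [ion for ion in derived if ion.annotation not in proposed]
        if not fresh and not new_matches:
            break
        proposed.update(ion.annotation for ion in fresh)
        pool.extend(fresh)

    for i, ion in assigned.items():
        peaks[i].annotation = ion.annotation
    total = sum(p.intensity for p in peaks) or 1.0
    annotated = sum(p.intensity for p in peaks if p.annotation is not None)
    logger.info(
        "annotated %d/%d peaks (%.1f%% intensity) of %s",
        len(assigned), len(peaks), 100.0 * annotated / total,
        entry.spectrum.identifier,
    )
    return out


def annotation_signature(
    tol_ppm: float,
    series: Iterable[str] = BASE_SERIES,
    depth: int = 15,
) -> str:
    """Deterministic fingerprint of annotation-relevant parameters.

    Stored in library Comment tokens; a mismatch at search time triggers
    re-annotation and decoy regeneration.
    """
    canonical = f"tol={tol_ppm:.6g};series={','.join(sorted(series))};depth={depth}"
    return hashlib.sha1(canonical.encode()).hexdigest()[:16]
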