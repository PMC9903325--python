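"""End-to-end library search: candidate selection by precursor tolerance,
scoring, per-spectrum ranking, and FDR estimation (target-decoy and
synthetic-pool)."""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import BASE_SERIES, annotate_spectrum, annotation_signature
from .decoy import is_annotated
from .domain import LibraryEntry, Spectrum
from .preprocessing import PreprocessParams, preprocess
from .scoring import DEFAULT_SCORING_SERIES, ScoreBreakdown, score_pair

logger = logging.getLogger(__name__)

#: "above the score threshold" is implemented as non-strict (S >= threshold).
THRESHOLD_INCLUSIVE = True


@dataclass(frozen=True)
class SearchParams:
    """Search configuration; defaults are the engine's standard HCD setup:
    10 ppm precursor / 20 ppm fragment tolerance, peak picking depth 15 per
    100 Th, y/b/internal scoring series."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    preprocessing: PreprocessParams = field(default_factory=PreprocessParams)
    scoring_series: frozenset[str] = DEFAULT_SCORING_SERIES


@dataclass
class PSM:
    """One scored spectrum-to-library-entry match."""

    spectrum_id: str
    entry: LibraryEntry
    breakdown: ScoreBreakdown
    rank: int = 1
    q_value: Optional[float] = None


@dataclass
class FdrSummary:
    threshold: float
    target_hits: int
    decoy_hits: int
    fdr: float
    undefined: bool = False
    correct_hits: int = 0
    incorrect_hits: int = 0
    synthetic_fdr: Optional[float] = None


class LibraryIndex:
    """Entries indexed by precursor charge with sorted precursor m/z arrays
    for windowed candidate lookup."""

    def __init__(self, entries: Sequence[LibraryEntry]):
        self._by_charge: dict[int, tuple[list[float], list[LibraryEntry]]] = {}
        buckets: dict[int, list[LibraryEntry]] = {}
        for entry in entries:
            buckets.setdefault(entry.spectrum.precursor_charge, []).append(entry)
        for charge, bucket in buckets.items():
            bucket.sort(key=lambda e: e.spectrum.precursor_mz)
            self._by_charge[charge] = (
                [e.spectrum.precursor_mz for e in bucket],
                bucket,
            )

    def select_candidates(
        self, s: Spectrum, prec_tol_ppm: float
    ) -> list[LibraryEntry]:
        """Entries with matching charge and |delta precursor m/z| within the
        closed ppm interval."""
        if s.precursor_charge not in self._by_charge:
            return []
        mzs, bucket = self._by_charge[s.precursor_charge]
        half = s.precursor_mz * prec_tol_ppm * 1e-6
        lo = bisect.bisect_left(mzs, s.precursor_mz - half - 1e-12)
        hi = bisect.bisect_right(mzs, s.precursor_mz + half + 1e-12)
        return [
            e
            for e in bucket[lo:hi]
            if abs(e.spectrum.precursor_mz - s.precursor_mz)
            <= half + 1e-12
        ]


def select_candidates(
    s: Spectrum, index: LibraryIndex, prec_tol_ppm: float
) -> list[LibraryEntry]:
    return index.select_candidates(s, prec_tol_ppm)


def prepare_library(
    entries: Sequence[LibraryEntry], params: SearchParams
) -> list[LibraryEntry]:
    """Annotate (where needed) and preprocess library entries once, keeping
    peak annotations through preprocessing."""
    prepared = []
    for entry in entries:
        if not entry.is_decoy and not is_annotated(entry):
            entry = annotate_spectrum(entry, params.fragment_tol_ppm)
        processed = entry.copy()
        processed.spectrum = preprocess(processed.spectrum, params.preprocessing)
        if processed.spectrum.flagged_empty:
            logger.warning(
                "library entry %s emptied by preprocessing; kept with no peaks",
                entry.spectrum.identifier,
            )
        prepared.append(processed)
    return prepared


def check_signature(
    entries: Sequence[LibraryEntry], params: SearchParams, depth: int = 15
) -> bool:
    """True when every entry carrying an AnnotSig token matches the current
    annotation-relevant parameters (mismatch should trigger re-annotation
    and decoy regeneration)."""
    expected = annotation_signature(
        params.fragment_tol_ppm, BASE_SERIES, params.preprocessing.depth
    )
    for entry in entries:
        stored = entry.comment_tokens.get("AnnotSig")
        if stored is not None and stored != expected:
            return False
    return True


def search_run(
    spectra: Sequence[Spectrum],
    library: Sequence[LibraryEntry],
    params: SearchParams | None = None,
    max_rank: int = 1,
) -> list[PSM]:
    """Search all spectra against a (target + decoy) library.

    Output is deterministic: spectrum order, then rank; per-spectrum ties in
    S break by larger matched peak count, then lexicographic peptide.
    Flagged-empty spectra are skipped with a log line.
    """
    params = params or SearchParams()
    prepared = prepare_library(library, params)
    index = LibraryIndex([e for e in prepared if e.spectrum.peaks])
    psms: list[PSM] = []
    for s in spectra:
        processed = preprocess(s, params.preprocessing)
        if processed.flagged_empty:
            logger.info("spectrum %s empty after preprocessing; skipped", s.identifier)
            continue
        candidates = index.select_candidates(processed, params.precursor_tol_ppm)
        scored = [
            PSM(
                spectrum_id=s.identifier,
                entry=entry,
                breakdown=score_pair(
                    processed,
                    entry,
                    params.fragment_tol_ppm,
                    params.scoring_series,
                ),
            )
            for entry in candidates
        ]
        scored.sort(
            key=lambda p: (
                -p.breakdown.S,
                -p.breakdown.n,
                p.entry.peptide.sequence,
            )
        )
        for rank, psm in enumerate(scored[:max_rank], start=1):
            psm.rank = rank
            psms.append(psm)
    return psms


def rank1(psms: Sequence[PSM]) -> list[PSM]:
    return [p for p in psms if p.rank == 1]


def compute_fdr(psms: Sequence[PSM], threshold: float) -> FdrSummary:
    """Target-decoy FDR = decoy hits / target hits among rank-1 PSMs with
    S >= threshold. With zero target hits the FDR is undefined and reported
    as 1.0 with a flag."""
    target_hits = decoy_hits = 0
    for psm in psms:
        if psm.breakdown.S >= threshold:
            if psm.entry.is_decoy:
                decoy_hits += 1
            else:
                target_hits += 1
    if target_hits == 0:
        return FdrSummary(threshold, 0, decoy_hits, 1.0, undefined=True)
    return FdrSummary(threshold, target_hits, decoy_hits, decoy_hits / target_hits)


def qvalues(psms: Sequence[PSM]) -> list[PSM]:
    """Assign q-values: sweep thresholds at each distinct S descending and
    monotonize the FDR by a running minimum from below."""
    order = sorted(range(len(psms)), key=lambda i: -psms[i].breakdown.S)
    targets = decoys = 0
    fdr_at: list[float] = [0.0] * len(psms)
    for pos, i in enumerate(order):
        if psms[i].entry.is_decoy:
            decoys += 1
        else:
            targets += 1
        fdr_at[pos] = decoys / targets if targets else 1.0
    running = 1.0
    qs: list[float] = [0.0] * len(psms)
    for pos in range(len(order) - 1, -1, -1):
        running = min(running, fdr_at[pos])
        qs[pos] = running
    for pos, i in enumerate(order):
        psms[i].q_value = qs[pos]
    return list(psms)


def score_at_qvalue(psms: Sequence[PSM], q: float = 0.01) -> Optional[float]:
    """Lowest score whose q-value is <= q (the acceptance threshold)."""
    accepted = [p.breakdown.S for p in psms if p.q_value is not None and p.q_value <= q]
    return min(accepted) if accepted else None


def synthetic_fdr(
    psms: Sequence[PSM],
    pool: Sequence[str],
    il_equivalent: bool = False,
) -> FdrSummary:
    """Synthetic-pool FDR = incorrect / (incorrect + correct) over accepted
    target PSMs; a hit is correct iff its stripped sequence equals a pool
    sequence or is a contiguous substring of one (truncated synthesis
    products)."""
    if not pool:
        raise ValueError("pool must be non-empty")

    def canon(seq: str) -> str:
        return seq.replace("I", "L") if il_equivalent else seq

    pool_seqs = [canon(s) for s in pool]
    correct = incorrect = 0
    for psm in psms:
        if psm.entry.is_decoy:
            continue
        seq = canon(psm.entry.peptide.stripped())
        if any(seq in p for p in pool_seqs):
            correct += 1
        else:
            incorrect += 1
    total = correct + incorrect
    return FdrSummary(
        threshold=float("nan"),
        target_hits=total,
        decoy_hits=0,
        fdr=float("nan"),
        correct_hits=correct,
        incorrect_hits=incorrect,
        synthetic_fdr=(incorrect / total) if total else 0.0,
    )
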