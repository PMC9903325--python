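"""Spectrum-to-spectrum scoring: composite score S = P * Q.

P is a probabilistic score combining, by Fisher's method, three p-values
computed on the matched peaks of an input/library spectrum pair:

* p_B   — cumulative binomial: probability of matching as many or more
          peaks by chance, with the chance-match probability p_match given
          by the fraction of the input's m/z span covered by tolerance
          windows around the library peaks (intensity-blind).
* p_KT  — exact Kendall-Tau: probability of an equal or better intensity
          rank correlation between the matched peaks, from the exact
          inversion-count frequency distribution f(q, n) (exact up to
          n = 170 matched peaks; normal approximation beyond).
* p_HG  — cumulative hypergeometric: probability of as many or more exact
          intensity-rank coincidences among the matched peaks.

Q is a quantitative score: the fraction of library intensity explained by
matched peaks annotated with a relevant ion series (default y, b and the
internal fragments derived from them).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

from scipy import stats

from .domain import LibraryEntry, Spectrum, ppm_error

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
EPS = 1e-9

#: Exact Kendall frequency distribution is used up to this many matched
#: peaks; beyond it the normal approximation to the inversion count applies.
EXACT_KENDALL_MAX_N = 170

#: Default scoring ion series for the quantitative score.
DEFAULT_SCORING_SERIES = frozenset({"y", "b", "internal"})


@dataclass
class PeakMatch:
    """One matched input/library peak pair. Ranks are intensity ranks within
    the full preprocessed spectra (1 = most intense)."""

    input_index: int
    library_index: int
    ppm_error: float
    input_rank: int = 0
    library_rank: int = 0


@dataclass
class ScoreBreakdown:
    """Everything the composite score is made of, exported as subscores."""

    S: float
    P: float
    Q: float
    p_B: float
    p_KT: float
    p_HG: float
    n: int
    p_match: float
    q: int
    q_max: int
    r: int
    N_I: int
    N_L: int
    N_max: int
    L_scoring: float
    L_total: float
    fisher_statistic: float
    combined_p: float
    per_series: dict[str, tuple[float, float]] = field(default_factory=dict)
    matches: list[PeakMatch] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Peak pairing

def match_peaks(s_I: Spectrum, s_L: Spectrum, tol_ppm: float) -> list[PeakMatch]:
    """One-to-one peak pairing, greedy by ascending |ppm error|.

    The tolerance window is relative to the library peak m/z. Each input and
    each library peak joins at most one pair.
    """
    lib_mzs = s_L.mzs
    candidates: list[tuple[float, int, int]] = []
    for i, peak in enumerate(s_I.peaks):
        half = peak.mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(lib_mzs, peak.mz - half - 1e-9)
        hi = bisect.bisect_right(lib_mzs, peak.mz + half + 1e-9)
        for j in range(lo, hi):
            err = ppm_error(peak.mz, lib_mzs[j])
            if abs(err) <= tol_ppm:
                candidates.append((abs(err), i, j))
    candidates.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    matches = []
    for _, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matches.append(
            PeakMatch(i, j, ppm_error(s_I.peaks[i].mz, s_L.peaks[j].mz))
        )
    matches.sort(key=lambda m: m.input_index)
    return matches


def match_probability(s_I: Spectrum, s_L: Spectrum, tol_ppm: float) -> float:
    """Chance probability of matching one peak: covered fraction of the
    input's m/z span (first to last peak) under the union of tolerance
    windows around the library peaks."""
    if not s_I.peaks or not s_L.peaks:
        raise ValueError("both spectra must be non-empty")
    first, last = s_I.peaks[0].mz, s_I.peaks[-1].mz
    span = last - first
    if span <= 0:
        logger.warning(
            "spectrum %s has zero m/z span; p_match clamped", s_I.identifier
        )
        return EPS
    covered = 0.0
    cur_lo = cur_hi = None
    for peak in s_L.peaks:
        half = peak.mz * tol_ppm * 1e-6
        lo = max(peak.mz - half, first)
        hi = min(peak.mz + half, last)
        if hi <= lo:
            continue
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        covered += cur_hi - cur_lo
    return min(max(covered / span, EPS), 1.0 - EPS)


# ---------------------------------------------------------------------------
# The three p-values

def binomial_pvalue(n: int, N_I: int, p_match: float) -> float:
    """Upper-tail cumulative binomial: P(X >= n) with X ~ Bin(N_I, p_match)."""
    if n > N_I:
        raise ValueError(f"matched peaks {n} exceed input peak count {N_I}")
    if not 0 < p_match < 1:
        raise ValueError("p_match must lie strictly in (0, 1)")
    if n <= 0:
        return 1.0
    return float(stats.binom.sf(n - 1, N_I, p_match))


@lru_cache(maxsize=32)
def kendall_frequency(n: int) -> tuple[int, ...]:
    """Exact inversion-count frequencies f(q, n) for q = 0 .. n(n-1)/2.

    f(q, n) counts permutations of n items with exactly q inversions, built
    by the recurrence f(q, n) = sum_{j=0}^{min(q, n-1)} f(q - j, n - 1) in
    exact integer arithmetic (sliding-window prefix sums).
    """
    if not 2 <= n <= EXACT_KENDALL_MAX_N:
        raise ValueError(
            f"exact frequency table supports 2 <= n <= {EXACT_KENDALL_MAX_N}"
        )
    f = [1]
    for m in range(2, n + 1):
        q_max = m * (m - 1) // 2
        prefix = [0] * (len(f) + 1)
        for i, value in enumerate(f):
            prefix[i + 1] = prefix[i] + value
        new = []
        for q in range(q_max + 1):
            hi = min(q, len(f) - 1)
            lo = max(0, q - m + 1)
            new.append(prefix[hi + 1] - prefix[lo])
        f = new
    return tuple(f)


def count_discordant(
    library_ranks: Sequence[int], input_ranks: Sequence[int]
) -> tuple[int, int]:
    """Discordant pair count q between two rank lists (= minimum adjacent
    transpositions to sort one into the other) and its maximum n(n-1)/2."""
    if len(library_ranks) != len(input_ranks):
        raise ValueError("rank lists must have equal length")
    n = len(library_ranks)
    if n < 2:
        raise ValueError("need at least two ranks")
    q = 0
    for i in range(n):
        for j in range(i + 1, n):
            if (library_ranks[i] - library_ranks[j]) * (
                input_ranks[i] - input_ranks[j]
            ) < 0:
                q += 1
    return q, n * (n - 1) // 2


def kendall_pvalue(q: int, n: int) -> float:
    """P(Q <= q) for the inversion count of a random permutation of n items:
    the probability of an equal or better rank correlation by chance.

    Exact (big-integer) for n <= 170; continuity-corrected normal
    approximation with mean q_max/2 and variance n(n-1)(2n+5)/72 beyond.
    """
    if n < 2:
        return 1.0
    q_max = n * (n - 1) // 2
    if not 0 <= q <= q_max:
        raise ValueError(f"q={q} outside [0, {q_max}]")
    if n <= EXACT_KENDALL_MAX_N:
        freq = kendall_frequency(n)
        favourable = sum(freq[: q + 1])
        return float(Fraction(favourable, math.factorial(n)))
    mean = q_max / 2.0
    var = n * (n - 1) * (2 * n + 5) / 72.0
    z = (q + 0.5 - mean) / math.sqrt(var)
    return float(stats.norm.cdf(z))


def hypergeometric_pvalue(n: int, r: int, N_max: int) -> float:
    """P(X >= r) with X hypergeometric: population N_max, n marked, n drawn —
    the chance of as many or more exact rank coincidences."""
    if n > N_max:
        raise ValueError(f"matched peaks {n} exceed N_max {N_max}")
    if not 0 <= r <= n:
        raise ValueError(f"rank coincidences r={r} outside [0, {n}]")
    if r <= 0:
        return 1.0
    return float(stats.hypergeom.sf(r - 1, N_max, n, n))


def fisher_combine(p_B: float, p_KT: float, p_HG: float) -> tuple[float, float]:
    """Fisher's method: X = -2 * sum(ln p); combined p = chi-square(6)
    survival at X. Inputs must be in (0, 1]."""
    ps = (p_B, p_KT, p_HG)
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = -2.0 * sum(math.log(p) for p in ps)
    return statistic, float(stats.chi2.sf(statistic, df=6))


# ---------------------------------------------------------------------------
# Quantitative score

def quantitative_score(
    matches: Sequence[PeakMatch],
    s_L: Spectrum,
    scoring_series: frozenset[str] = DEFAULT_SCORING_SERIES,
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Fraction of library intensity in scoring peaks: matched AND annotated
    with a relevant ion series. Also reports absolute and relative matched
    intensity per ion series."""
    L_total = math.fsum(p.intensity for p in s_L.peaks)
    if L_total <= 0:
        raise ValueError("library spectrum has zero total intensity")
    per_series_abs: dict[str, float] = {}
    L_scoring = 0.0
    for m in matches:
        peak = s_L.peaks[m.library_index]
        if peak.annotation is None:
            continue
        series = peak.annotation.series
        per_series_abs[series] = per_series_abs.get(series, 0.0) + peak.intensity
        if series in scoring_series:
            L_scoring += peak.intensity
    per_series = {
        series: (absolute, absolute / L_total)
        for series, absolute in per_series_abs.items()
    }
    return L_scoring / L_total, per_series


# ---------------------------------------------------------------------------
# Composite score

def intensity_ranks(s: Spectrum) -> list[int]:
    """Intensity ranks, 1 = most intense; ties broken by ascending m/z."""
    order = sorted(
        range(len(s.peaks)),
        key=lambda i: (-s.peaks[i].intensity, s.peaks[i].mz),
    )
    ranks = [0] * len(s.peaks)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def _subset_ranks(values: Sequence[tuple[float, float]]) -> list[int]:
    """Ranks within a matched subset by (intensity desc, m/z asc)."""
    order = sorted(range(len(values)), key=lambda i: (-values[i][0], values[i][1]))
    ranks = [0] * len(values)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def _clamp(p: float) -> float:
    return min(max(p, P_FLOOR), 1.0)


def score_pair(
    s_I: Spectrum,
    entry: LibraryEntry,
    tol_ppm: float = 20.0,
    scoring_series: frozenset[str] = DEFAULT_SCORING_SERIES,
) -> ScoreBreakdown:
    """Score one preprocessed input spectrum against one annotated library
    entry; returns the full breakdown (S, P, Q, the three p-values, counts,
    per-series matched intensities)."""
    s_L = entry.spectrum
    N_I, N_L = len(s_I.peaks), len(s_L.peaks)
    N_max = max(N_I, N_L)
    matches = match_peaks(s_I, s_L, tol_ppm)
    n = len(matches)
    if n == 0:
        return ScoreBreakdown(
            S=0.0, P=0.0, Q=0.0, p_B=1.0, p_KT=1.0, p_HG=1.0, n=0,
            p_match=EPS, q=0, q_max=0, r=0, N_I=N_I, N_L=N_L, N_max=N_max,
            L_scoring=0.0,
            L_total=math.fsum(p.intensity for p in s_L.peaks),
            fisher_statistic=0.0, combined_p=1.0, per_series={}, matches=[],
        )

    p_match = match_probability(s_I, s_L, tol_ppm)
    p_B = binomial_pvalue(n, N_I, p_match)

    in_ranks = intensity_ranks(s_I)
    lib_ranks = intensity_ranks(s_L)
    r = 0
    for m in matches:
        m.input_rank = in_ranks[m.input_index]
        m.library_rank = lib_ranks[m.library_index]
        if m.input_rank == m.library_rank:
            r += 1
    p_HG = hypergeometric_pvalue(n, r, N_max)

    if n >= 2:
        sub_in = _subset_ranks(
            [(s_I.peaks[m.input_index].intensity, s_I.peaks[m.input_index].mz)
             for m in matches]
        )
        sub_lib = _subset_ranks(
            [(s_L.peaks[m.library_index].intensity, s_L.peaks[m.library_index].mz)
             for m in matches]
        )
        q, q_max = count_discordant(sub_lib, sub_in)
        p_KT = kendall_pvalue(q, n)
    else:
        q, q_max, p_KT = 0, 0, 1.0

    statistic, combined_p = fisher_combine(
        _clamp(p_B), _clamp(p_KT), _clamp(p_HG)
    )
    P = -math.log10(_clamp(combined_p))
    Q, per_series = quantitative_score(matches, s_L, scoring_series)
    return ScoreBreakdown(
        S=P * Q, P=P, Q=Q, p_B=p_B, p_KT=p_KT, p_HG=p_HG, n=n,
        p_match=p_match, q=q, q_max=q_max, r=r, N_I=N_I, N_L=N_L, N_max=N_max,
        L_scoring=Q * math.fsum(p.intensity for p in s_L.peaks),
        L_total=math.fsum(p.intensity for p in s_L.peaks),
        fisher_statistic=statistic, combined_p=combined_p,
        per_series=per_series, matches=matches,
    )
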