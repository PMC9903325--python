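"""Scoring subcomponents against independent brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import speclib as sl
from speclib.scoring import (
    EXACT_KENDALL_MAX_N,
    P_FLOOR,
    ScoreBreakdown,
    score_pair,
)


# ---------------------------------------------------------------------------
# binomial

def _binomial_tail_enum(n, N, p):
    return math.fsum(
        math.comb(N, k) * p**k * (1 - p) ** (N - k) for k in range(n, N + 1)
    )


@pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.9])
def test_binomial_pvalue_matches_term_enumeration(p):
    for N in range(1, 13):
        for n in range(0, N + 1):
            expected = _binomial_tail_enum(n, N, p)
            assert sl.binomial_pvalue(n, N, p) == pytest.approx(
                expected, abs=1e-12
            )


def test_binomial_pvalue_edge_cases():
    assert sl.binomial_pvalue(0, 5, 0.3) == 1.0
    assert sl.binomial_pvalue(3, 3, 0.5) == pytest.approx(0.125, abs=1e-15)
    assert sl.binomial_pvalue(2, 3, 0.5) == pytest.approx(0.5, abs=1e-15)
    with pytest.raises(ValueError):
        sl.binomial_pvalue(4, 3, 0.5)
    with pytest.raises(ValueError):
        sl.binomial_pvalue(1, 3, 0.0)


# ---------------------------------------------------------------------------
# Kendall frequency distribution and p-value

def _inversions(perm):
    return sum(
        1
        for i, j in itertools.combinations(range(len(perm)), 2)
        if perm[i] > perm[j]
    )


@pytest.mark.parametrize("n", range(2, 8))
def test_kendall_frequency_matches_permutation_enumeration(n):
    counts = [0] * (n * (n - 1) // 2 + 1)
    for perm in itertools.permutations(range(n)):
        counts[_inversions(perm)] += 1
    assert list(sl.kendall_frequency(n)) == counts


@pytest.mark.parametrize("n", range(2, 11))
def test_kendall_frequency_sum_and_symmetry(n):
    freq = sl.kendall_frequency(n)
    assert sum(freq) == math.factorial(n)
    assert freq == freq[::-1]  # reversal bijection q <-> q_max - q


def test_kendall_frequency_exact_at_170():
    freq = sl.kendall_frequency(170)
    assert len(freq) == 170 * 169 // 2 + 1
    assert sum(freq) == math.factorial(170)  # exact big-int, no overflow


@pytest.mark.parametrize("n", [3, 5])
def test_kendall_pvalue_matches_enumeration(n):
    total = math.factorial(n)
    for q in range(n * (n - 1) // 2 + 1):
        favourable = sum(
            1
            for perm in itertools.permutations(range(n))
            if _inversions(perm) <= q
        )
        assert sl.kendall_pvalue(q, n) == pytest.approx(
            favourable / total, abs=1e-12
        )


def test_kendall_pvalue_edges_and_approximation():
    assert sl.kendall_pvalue(0, 3) == pytest.approx(1 / 6, abs=1e-15)
    assert sl.kendall_pvalue(3, 3) == 1.0
    assert sl.kendall_pvalue(0, 1) == 1.0
    with pytest.raises(ValueError):
        sl.kendall_pvalue(-1, 5)
    # beyond the exact cap the normal approximation takes over and is a
    # proper lower-tail probability centred at q_max / 2
    n = EXACT_KENDALL_MAX_N + 10
    q_max = n * (n - 1) // 2
    mid = sl.kendall_pvalue(q_max // 2, n)
    assert 0.45 < mid < 0.55
    assert sl.kendall_pvalue(0, n) < 1e-6
    assert sl.kendall_pvalue(q_max, n) > 0.999


@settings(derandomize=True, max_examples=50)
@given(st.permutations(list(range(1, 7))))
def test_count_discordant_equals_bubble_sort_swaps(perm):
    identity = list(range(1, 7))
    q, q_max = sl.count_discordant(identity, perm)
    assert q_max == 15
    work, swaps = list(perm), 0
    changed = True
    while changed:
        changed = False
        for i in range(len(work) - 1):
            if work[i] > work[i + 1]:
                work[i], work[i + 1] = work[i + 1], work[i]
                swaps += 1
                changed = True
    assert q == swaps


def test_count_discordant_extremes():
    assert sl.count_discordant([1, 2, 3], [1, 2, 3]) == (0, 3)
    assert sl.count_discordant([1, 2, 3], [3, 2, 1]) == (3, 3)
    with pytest.raises(ValueError):
        sl.count_discordant([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# hypergeometric

def _hypergeom_tail_enum(n, r, N_max):
    """Enumerate all draws of n items from a population of N_max with n
    marked; count draws with >= r marked."""
    population = range(N_max)
    marked = set(range(n))
    hits = total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= r:
            hits += 1
    return hits / total


def test_hypergeometric_pvalue_matches_draw_enumeration():
    for N_max in range(1, 13):
        for n in range(0, N_max + 1):
            for r in range(0, n + 1):
                expected = _hypergeom_tail_enum(n, r, N_max)
                assert sl.hypergeometric_pvalue(n, r, N_max) == pytest.approx(
                    expected, abs=1e-12
                )


def test_hypergeometric_pvalue_examples():
    assert sl.hypergeometric_pvalue(5, 0, 10) == 1.0
    assert sl.hypergeometric_pvalue(2, 2, 4) == pytest.approx(1 / 6, abs=1e-15)
    with pytest.raises(ValueError):
        sl.hypergeometric_pvalue(5, 1, 4)


# ---------------------------------------------------------------------------
# Fisher combination

def test_fisher_combine_properties():
    stat, p = sl.fisher_combine(1.0, 1.0, 1.0)
    assert stat == 0.0 and p == 1.0
    for perm in itertools.permutations([0.02, 0.3, 0.7]):
        stat_p, p_p = sl.fisher_combine(*perm)
        stat0, p0 = sl.fisher_combine(0.02, 0.3, 0.7)
        assert stat_p == pytest.approx(stat0, abs=1e-14)
        assert p_p == pytest.approx(p0, abs=1e-14)
    with pytest.raises(ValueError):
        sl.fisher_combine(0.0, 0.5, 0.5)


def test_fisher_combine_matches_chi2_quadrature():
    for ps in [(0.1, 0.1, 0.1), (0.5, 0.2, 0.9), (0.01, 0.8, 0.3)]:
        stat, p = sl.fisher_combine(*ps)
        assert stat == pytest.approx(-2 * sum(math.log(x) for x in ps))
        quad, _ = integrate.quad(lambda x: stats.chi2.pdf(x, 6), stat, np.inf)
        assert p == pytest.approx(quad, abs=1e-10)


# ---------------------------------------------------------------------------
# peak matching and p_match

def _spec(mzs, intensities=None, **kw):
    intensities = intensities or [1.0] * len(mzs)
    return sl.Spectrum(
        identifier=kw.get("identifier", "t"),
        precursor_mz=kw.get("precursor_mz", 1000.0),
        precursor_charge=kw.get("charge", 2),
        peaks=[sl.Peak(m, i) for m, i in zip(mzs, intensities)],
    )


def test_match_peaks_identity_and_disjoint():
    a = _spec([200.0, 300.0, 400.0])
    matches = sl.match_peaks(a, a, 20.0)
    assert len(matches) == 3
    assert all(m.ppm_error == 0.0 for m in matches)
    b = _spec([250.0, 350.0])
    assert sl.match_peaks(a, b, 20.0) == []


def test_match_peaks_one_to_one_and_greedy_optimality(rng):
    """On small instances where the greedy choice is unambiguous, greedy
    pairing equals the brute-force minimum-total-|error| assignment."""
    for _ in range(25):
        base = rng.uniform(300, 800, size=4)
        lib = _spec(sorted(base))
        offsets = rng.uniform(-8, 8, size=4)  # ppm, well inside tol
        inp = _spec(sorted(base * (1 + offsets * 1e-6)))
        matches = sl.match_peaks(inp, lib, 20.0)
        assert len({m.input_index for m in matches}) == len(matches)
        assert len({m.library_index for m in matches}) == len(matches)
        # brute force over all assignments of equal size
        nI, nL = len(inp.peaks), len(lib.peaks)
        errs = {}
        for i in range(nI):
            for j in range(nL):
                e = abs(sl.ppm_error(inp.peaks[i].mz, lib.peaks[j].mz))
                if e <= 20.0:
                    errs[(i, j)] = e
        best, best_cost = None, None
        for size in range(min(nI, nL), -1, -1):
            for iset in itertools.permutations(range(nI), size):
                for jset in itertools.combinations(range(nL), size):
                    pairs = list(zip(iset, jset))
                    if any(p not in errs for p in pairs):
                        continue
                    cost = sum(errs[p] for p in pairs)
                    if best is None or cost < best_cost:
                        best, best_cost = pairs, cost
            if best is not None:
                break
        assert len(matches) == len(best)
        greedy_cost = sum(abs(m.ppm_error) for m in matches)
        assert greedy_cost == pytest.approx(best_cost, rel=1e-6)


def test_match_probability_interval_union(rng):
    lib = _spec([400.0, 400.004])  # heavily overlapping windows at 20 ppm
    inp = _spec([300.0, 500.0])
    p = sl.match_probability(inp, lib, 20.0)
    # brute-force merged union of the two clipped intervals
    halves = [mz * 20e-6 for mz in (400.0, 400.004)]
    lo = min(400.0 - halves[0], 400.004 - halves[1])
    hi = max(400.0 + halves[0], 400.004 + halves[1])
    assert p == pytest.approx((hi - lo) / 200.0, rel=1e-9)
    # non-overlapping additivity
    lib2 = _spec([350.0, 450.0])
    w = 350.0 * 40e-6 + 450.0 * 40e-6
    assert sl.match_probability(inp, lib2, 20.0) == pytest.approx(
        w / 200.0, rel=1e-9
    )
    # full coverage clamps just below one
    dense = _spec(list(np.linspace(300, 500, 2000)))
    assert sl.match_probability(inp, dense, 200.0) == pytest.approx(1.0, abs=1e-6)


def test_match_probability_random_intervals_vs_merge_oracle(rng):
    for _ in range(20):
        lib_mzs = sorted(rng.uniform(310, 690, size=15))
        lib = _spec(lib_mzs)
        inp = _spec([300.0, 700.0])
        tol = 300.0
        intervals = []
        for mz in lib_mzs:
            half = mz * tol * 1e-6
            intervals.append((max(mz - half, 300.0), min(mz + half, 700.0)))
        merged = []
        for lo, hi in sorted(intervals):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        expected = sum(hi - lo for lo, hi in merged) / 400.0
        assert sl.match_probability(inp, lib, tol) == pytest.approx(
            min(expected, 1 - 1e-9), rel=1e-9
        )


# ---------------------------------------------------------------------------
# quantitative score and composite score

def _annotated_entry():
    peptide = sl.Peptide("PEPTIDEK", [], 2)
    entry = sl.LibraryEntry(
        peptide=peptide,
        spectrum=sl.Spectrum(
            identifier="e",
            precursor_mz=peptide.precursor_mz,
            precursor_charge=2,
            peaks=[
                sl.Peak(peptide.fragment_mz(sl.IonAnnotation(series="y", ordinal=o)), 10.0)
                for o in range(1, 8)
            ],
        ),
    )
    return sl.annotate_spectrum(entry, 20.0)


def test_quantitative_score_ratio_cases():
    entry = _annotated_entry()
    s_L = entry.spectrum
    matches = sl.match_peaks(s_L, s_L, 20.0)
    q, per_series = sl.quantitative_score(matches, s_L)
    assert q == pytest.approx(1.0)
    assert per_series["y"][1] == pytest.approx(1.0)
    assert sl.quantitative_score([], s_L) == (0.0, {})
    # half the intensity matched: keep only peaks covering half the total
    half_matches = matches[: len(matches) // 2 + 1]
    target = sum(s_L.peaks[m.library_index].intensity for m in half_matches)
    qh, _ = sl.quantitative_score(half_matches, s_L)
    assert qh == pytest.approx(target / sum(p.intensity for p in s_L.peaks))


def test_score_pair_self_match_dominates(fixture_library):
    params = sl.PreprocessParams()
    processed = []
    for entry in fixture_library[:10]:
        e = entry.copy()
        e.spectrum = sl.preprocess(e.spectrum, params)
        processed.append(e)
    for i, entry in enumerate(processed):
        self_score = score_pair(entry.spectrum, entry).S
        b = score_pair(entry.spectrum, entry)
        assert b.n == b.N_L and b.q == 0 and b.r == b.n
        assert b.Q == pytest.approx(1.0)
        for j, other in enumerate(processed):
            if i != j:
                assert score_pair(entry.spectrum, other).S < self_score


def test_score_pair_no_matches_is_valid_zero():
    a = _spec([200.0, 300.0, 400.0])
    peptide = sl.Peptide("ELVISLIVESK", [], 2)
    entry = sl.LibraryEntry(
        peptide=peptide,
        spectrum=_spec([650.0, 750.0], identifier="far", precursor_mz=peptide.precursor_mz),
    )
    b = score_pair(a, entry, 20.0)
    assert b.S == 0.0 and b.Q == 0.0
    assert b.p_B == b.p_KT == b.p_HG == 1.0


def test_composite_score_monotonicity():
    """S increases with Q at fixed p-values and decreases as any p-value
    rises; exercised through the isolated combination formula."""
    import math as _m

    def S(pB, pKT, pHG, Q):
        stat, comb = sl.fisher_combine(pB, pKT, pHG)
        return -_m.log10(max(comb, P_FLOOR)) * Q

    grid = [0.001, 0.05, 0.5]
    for pB in grid:
        for pKT in grid:
            for pHG in grid:
                assert S(pB, pKT, pHG, 0.9) > S(pB, pKT, pHG, 0.3)
                assert S(pB, pKT, pHG, 0.5) > S(min(pB * 10, 1.0), pKT, pHG, 0.5) or pB * 10 > 1
                assert S(pB, pKT, pHG, 0.5) > S(pB, min(pKT * 10, 1.0), pHG, 0.5) or pKT * 10 > 1


def test_score_breakdown_invariants_on_random_pairs(fixture_library, rng):
    params = sl.PreprocessParams()
    entries = []
    for entry in fixture_library[:15]:
        e = entry.copy()
        e.spectrum = sl.preprocess(e.spectrum, params)
        entries.append(e)
    for _ in range(30):
        i, j = rng.integers(0, len(entries), size=2)
        b = score_pair(entries[i].spectrum, entries[j])
        assert 0.0 <= b.Q <= 1.0
        assert all(0.0 < p <= 1.0 for p in (b.p_B, b.p_KT, b.p_HG))
        assert b.N_max == max(b.N_I, b.N_L)
        assert 0 <= b.q <= b.q_max <= b.n * (b.n - 1) // 2 if b.n >= 2 else True
        assert b.L_scoring <= b.L_total + 1e-9
        assert 0 <= b.r <= b.n


def test_score_pair_deterministic(fixture_library):
    params = sl.PreprocessParams()
    e0 = fixture_library[0].copy()
    e0.spectrum = sl.preprocess(e0.spectrum, params)
    e1 = fixture_library[1].copy()
    e1.spectrum = sl.preprocess(e1.spectrum, params)
    a = score_pair(e0.spectrum, e1)
    b = score_pair(e0.spectrum, e1)
    assert (a.S, a.P, a.Q, a.p_B, a.p_KT, a.p_HG) == (
        b.S, b.P, b.Q, b.p_B, b.p_KT, b.p_HG
    )
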