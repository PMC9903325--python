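# Methods

## Problem and approach

`speclib` identifies peptides in tandem (MS/MS) mass spectra by spectral
library searching: each query spectrum is compared to a library of reference
spectra of known peptides, and the best-scoring spectrum-to-spectrum match
becomes a peptide-spectrum match (PSM). Confidence is controlled by the
target-decoy approach, with decoy spectra generated from the target library
itself by shuffle-and-reposition.

## Preprocessing

Input and library spectra go through the same three steps so their peak
counts and intensity ranks are comparable:

1. **Unspecific-ion removal.** Peaks below `low_mass_cutoff` (default
   145 Th, below the smallest singly charged y1 of practical interest and
   excluding the immonium region) are dropped, as are peaks within
   `precursor_window` (default 2 Th half-width, wide enough for isotope
   envelopes at survey resolution) of the precursor, its charge-reduced
   species at charges z, z−1, …, 1, and their −H2O/−NH3 satellites.
2. **Peak picking.** Within each fixed window [100k, 100(k+1)) Th, only the
   `depth` (default 15) most intense peaks survive. Fixed bins rather than
   sliding windows: simplest deterministic reading of a per-100-Th depth,
   and parameterized. Intensity ties keep the lower-m/z peak, so the result
   is seed-free.
3. **Normalization.** Intensities are scaled to sum to
   `normalization_total` (100; arbitrary since only ratios and ranks matter
   downstream).

The pipeline is idempotent and order-stable; an emptied spectrum is flagged
and skipped by the search with a log line.

## The composite score

For a preprocessed input spectrum s_I (N_I peaks) and library spectrum s_L
(N_L peaks), peaks are paired one-to-one greedily by ascending |ppm error|
within the fragment tolerance (20 ppm default). Greedy pairing rather than
optimal assignment: it is deterministic, linear-ish, and equals the optimal
assignment whenever the choice is unambiguous (oracle-tested on small
instances). With n matched pairs:

* **p_B** — upper-tail binomial P(X ≥ n), X ~ Bin(N_I, p_match), where
  p_match is the fraction of s_I's m/z span (first to last peak) covered by
  the union of ±tol windows around s_L's peaks, clamped to [1e−9, 1−1e−9].
  Intensity-blind by construction.
* **p_KT** — lower-tail probability of the inversion count q between the
  matched peaks' intensity ranks (re-ranked within the matched subset),
  from the exact frequency distribution f(q, n) of inversions of a random
  permutation. f is built by the recurrence
  f(q, n) = Σ_{j=0..min(q,n−1)} f(q−j, n−1) with native big integers and a
  sliding-window prefix sum, exact up to n = 170; beyond that a
  continuity-corrected normal approximation with mean q_max/2 and variance
  n(n−1)(2n+5)/72 takes over. Fewer inversions = better correlation, hence
  the lower tail.
* **p_HG** — upper-tail hypergeometric P(X ≥ r) with population
  N_max = max(N_I, N_L), n marked items and n draws, where r counts matched
  pairs whose full-spectrum intensity ranks coincide exactly. Full-spectrum
  ranks use 1 = most intense with m/z-ascending tie-break.

The three p-values (clamped to [1e−300, 1]) combine by Fisher's method:
X = −2(ln p_B + ln p_KT + ln p_HG), combined p = upper tail of χ²(6). The
probabilistic score is P = −log10(combined p).

The quantitative score Q = L_scoring / L_total is the fraction of library
intensity in *scoring peaks*: peaks both matched and annotated with a
relevant series (default y, b, and internal fragments derived from them).

The composite score is **S = P · Q**: P scales with the improbability of the
match, Q gates it on explainable fragment intensity; the product preserves
both monotonicities. The combination lives in one place (`score_pair`) so
alternates are one-line changes. All subscores, counts and per-series
matched intensities are exported for downstream rescoring.

## Annotation expert system

Library spectra are annotated iteratively: generation 0 proposes b/y ions at
charges 1..min(2, precursor charge) — keeping the first pass specific —
matches them at the fragment tolerance, then derives from each confirmed
match (a) −H2O / −NH3 satellites gated on the spanned residues (S/T/E/D for
water, K/R/N/Q for ammonia) and (b) internal fragments (length ≥ 2,
excluding either terminus, b-type masses) from a second backbone cleavage of
matched b/y ions. The loop repeats until no new peak is annotated; it is
bounded by the peak count. Each peak gets at most one annotation; conflicts
resolve by a fixed priority table (y < b < y-loss < b-loss < a < a-loss <
internal < immonium), ties by smaller ppm error, then a deterministic
structural key — the result is independent of peak input order. A short
SHA-1-based signature of the annotation-relevant parameters is stored in the
library Comment; a mismatch at search time triggers re-annotation and decoy
regeneration, because decoys inherit the annotation tolerance.

## Decoy generation

For each annotated target entry, the peptide's interior residues are
shuffled uniformly with both termini fixed; positioned modifications travel
with their residue instance (terminus mods never move). The shuffle is
accepted when the Kendall-Tau correlation between the identity and the
resulting positional permutation is ≤ 0.5; otherwise it retries, up to
len(sequence)² attempts, after which no decoy is emitted (logged). Residue
*instances* are tracked, so tau is well defined for repeated amino acids.
Sequences of length ≤ 3 have an interior of fewer than two residues and
produce no decoy.

Each annotated peak then moves by δ = m/z(ion | decoy) − m/z(ion | target)
at the annotation's charge, preserving its intensity and its original
calibration error. Peaks shifted outside the detectable range (default: the
target spectrum's observed [first, last] m/z) are discarded; unannotated
peaks are copied verbatim. Internal-fragment bounds are conserved as
positional intervals applied to the decoy sequence. Precursor mass is
conserved exactly (permutation invariance), so decoys compete in the same
precursor windows as their targets. Per-entry RNG streams derive from
(seed, entry index), making the decoy library order-stable and
byte-reproducible.

## Search and FDR

Candidates are selected by charge equality and |Δ precursor m/z| within a
closed 10 ppm interval (sorted-array window lookup). Every candidate is
scored; PSMs are ranked per spectrum by S descending, ties broken by larger
n then lexicographic peptide, so output is deterministic. Only rank-1 PSMs
enter FDR estimation (spectrum-level competition between target and decoy).

FDR(t) = decoy hits / target hits among rank-1 PSMs with S ≥ t (non-strict,
an isolated constant); q-values monotonize FDR by a running minimum from
below. With zero target hits the FDR is reported as 1.0 with a flag.

Synthetic-pool validation declares a target hit *correct* iff its stripped
sequence equals a pool sequence or is a contiguous substring of one
(truncated synthesis products); synthetic FDR = incorrect / (incorrect +
correct). I and L are distinct by default (configurable flag); modified
peptides compare by stripped sequence.

## Synthetic fixtures

The generator emulates a synthetic-peptide-pool experiment at desk scale:
unique tryptic-style peptides (length 7–16, C-terminal K/R, no interior
K/R), singly charged b/y fragment spectra with rank-exponential intensities
(intensity ∝ exp(−rank/10), a realistic dynamic range with deterministic
ranks), Gaussian m/z jitter (5 ppm default), fragment dropout (20%), and 20
uniform-random noise peaks per spectrum drawn over
[low-mass cutoff, precursor m/z × z] with intensities from the lowest
quartile of the fragment intensities. Validation runs mix pool and off-pool
spectra at a configurable weight (default 0.8) and emit a truth table.

What the fixtures do **not** emulate: isotope envelopes, multiply charged
fragments, co-isolated chimeric spectra, learned intensity profiles, and
consensus-library averaging artifacts. Passing recovery tests therefore
demonstrates the engine's correctness and calibration under clean,
known-truth conditions, not its sensitivity on instrument data. Default
problem sizes (200-entry libraries, 200-spectrum runs, 500-entry decoy
sweeps) are the package's chosen desk-scale study conditions.

## Numerical choices

* Monoisotopic masses; proton 1.00727646688 Da; residue masses from
  pyteomics; built-in modification table (Carbamidomethyl +57.02146,
  Oxidation +15.99491) — the only modifications the default searches use.
* ppm error = 1e6 · (observed − theoretical)/theoretical; matching windows
  are relative to the library/theoretical m/z.
* p-values clamped to [1e−300, 1] before logs; p_match to [1e−9, 1−1e−9].
* Exact Kendall arithmetic uses Python integers and `fractions.Fraction` —
  no overflow at n = 170 (table size 14,366).
* Degenerate inputs: all-zero intensities raise; single-peak input spans
  clamp p_match with a warning; n = 0 pairs score S = 0 with p-values 1
  (a valid no-evidence result).

## Known limitations

* The annotator's neutral-loss catalogue and gating residues are a
  documented default, not an exhaustive HCD loss model.
* Greedy peak pairing can differ from the optimal assignment in contrived
  near-tie grids.
* The hypergeometric population parameterization (N_max, n marked, n drawn)
  is one self-consistent reading of "rank coincidences among matched
  peaks"; it is isolated in one function.
* No deisotoping or charge deconvolution; c/z/x ions (ETD) are out of
  scope.
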