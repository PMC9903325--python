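"""Synthetic peptides, spectra and libraries for validation without
downloads.

The generator emulates, at desk scale, the synthetic-peptide-pool study
design: tryptic-style peptides (length >= 7, C-terminal K/R), theoretical
b/y fragment spectra with configurable mass jitter, peak dropout and noise
peaks, and mixed validation runs pairing a pool library with off-pool
spectra plus a truth table.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import annotate_spectrum
from .domain import IonAnnotation, LibraryEntry, Peak, Peptide, Spectrum
from .io_formats import write_mgf, write_msp

logger = logging.getLogger(__name__)

#: Residues allowed in peptide interiors: the 20 standard amino acids minus
#: K/R (fully tryptic: no missed cleavages).
_INTERIOR_RESIDUES = np.array(list("ACDEFGHLMNPQSTVWY"))
_TERMINAL_RESIDUES = np.array(list("KR"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic fixtures.

    noise_peaks, jitter_ppm and dropout_fraction set the per-spectrum noise
    regime; the defaults (20 noise peaks, 5 ppm Gaussian mass error, 20%
    fragment dropout) are the noisy-run conditions the recovery checks use.
    """

    n_peptides: int = 200
    length_range: tuple[int, int] = (7, 16)
    charge_range: tuple[int, int] = (2, 3)
    noise_peaks: int = 20
    intensity_model: str = "rank_exponential"
    intensity_tau: float = 10.0
    jitter_ppm: float = 5.0
    dropout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 0 or self.noise_peaks < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.intensity_model not in ("uniform", "rank_exponential"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")


def generate_peptides(cfg: SimConfig) -> list[Peptide]:
    """Unique random tryptic-style peptides (C-terminal K/R, length >= 7 by
    default), reproducible from the config seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    peptides: list[Peptide] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = max(1000, 50 * cfg.n_peptides)
    while len(peptides) < cfg.n_peptides:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot draw {cfg.n_peptides} unique peptides of length "
                f"{cfg.length_range}"
            )
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_INTERIOR_RESIDUES, size=length - 1)) + str(
            rng.choice(_TERMINAL_RESIDUES)
        )
        if seq in seen:
            continue
        seen.add(seq)
        charge = int(rng.integers(cfg.charge_range[0], cfg.charge_range[1] + 1))
        peptides.append(Peptide(seq, [], charge))
    return peptides


def _fragment_annotations(peptide: Peptide) -> list[IonAnnotation]:
    anns = []
    for ordinal in range(1, len(peptide.sequence)):
        anns.append(IonAnnotation(series="b", ordinal=ordinal, charge=1))
        anns.append(IonAnnotation(series="y", ordinal=ordinal, charge=1))
    return anns


def simulate_spectrum(
    peptide: Peptide,
    cfg: SimConfig,
    rng: np.random.Generator,
    identifier: Optional[str] = None,
    low_mass_cutoff: float = 145.0,
) -> Spectrum:
    """Singly charged b/y fragment peaks with Gaussian ppm jitter, dropout,
    model intensities and uniform-random noise peaks."""
    anns = _fragment_annotations(peptide)
    mzs = np.array([peptide.fragment_mz(a) for a in anns])
    k = len(mzs)
    order = rng.permutation(k)  # intensity rank assignment
    if cfg.intensity_model == "rank_exponential":
        ranked = np.exp(-np.arange(1, k + 1) / cfg.intensity_tau)
        intensities = np.empty(k)
        intensities[order] = ranked
    else:
        intensities = rng.uniform(0.1, 1.0, size=k)
    keep = rng.random(k) >= cfg.dropout_fraction
    if cfg.jitter_ppm > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, cfg.jitter_ppm, size=k) * 1e-6)
    peaks = [
        Peak(float(mz), float(inten))
        for mz, inten, k_ in zip(mzs, intensities, keep)
        if k_
    ]
    if cfg.noise_peaks:
        upper = peptide.precursor_mz * peptide.charge
        noise_mz = rng.uniform(low_mass_cutoff, upper, size=cfg.noise_peaks)
        frag_int = intensities[keep]
        if frag_int.size:
            lo_int = float(frag_int.min())
            hi_int = float(np.quantile(frag_int, 0.25))
        else:
            lo_int, hi_int = 0.01, 0.05
        noise_int = rng.uniform(lo_int, max(hi_int, lo_int * 1.001), size=cfg.noise_peaks)
        peaks.extend(
            Peak(float(mz), float(inten))
            for mz, inten in zip(noise_mz, noise_int)
        )
    return Spectrum(
        identifier=identifier or f"sim_{peptide.sequence}_{peptide.charge}",
        precursor_mz=peptide.precursor_mz,
        precursor_charge=peptide.charge,
        peaks=peaks,
    )


def build_fixture_library(
    peptides: Sequence[Peptide],
    cfg: SimConfig,
    path: Optional[str | Path] = None,
    tol_ppm: float = 20.0,
) -> list[LibraryEntry]:
    """One annotated low-noise entry per peptide (no jitter, no dropout, no
    noise peaks); optionally written to an MSP file."""
    clean = replace(cfg, jitter_ppm=0.0, dropout_fraction=0.0, noise_peaks=0)
    entries = []
    for i, peptide in enumerate(peptides):
        rng = np.random.default_rng([cfg.seed, 1, i])
        spectrum = simulate_spectrum(
            peptide, clean, rng, identifier=f"{peptide.sequence}/{peptide.charge}"
        )
        entry = LibraryEntry(peptide=peptide, spectrum=spectrum, origin="fixture")
        entries.append(annotate_spectrum(entry, tol_ppm))
    if path is not None:
        write_msp(entries, path)
    return entries


def build_validation_run(
    pool: Sequence[Peptide],
    off_pool: Sequence[Peptide],
    cfg: SimConfig,
    n_spectra: Optional[int] = None,
    pool_weight: float = 0.8,
    mgf_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """A mixed run: each spectrum is generated from a pool peptide with
    probability ``pool_weight``, else from an off-pool peptide; the truth
    table maps every spectrum id to its generating peptide."""
    pool_set = {p.sequence for p in pool}
    if pool_set & {p.sequence for p in off_pool}:
        raise ValueError("pool and off_pool must be disjoint")
    if not pool or not off_pool:
        raise ValueError("pool and off_pool must be non-empty")
    n_spectra = n_spectra if n_spectra is not None else cfg.n_peptides
    rng = np.random.default_rng([cfg.seed, 2])
    spectra: list[Spectrum] = []
    rows = []
    for i in range(n_spectra):
        from_pool = bool(rng.random() < pool_weight)
        source = pool if from_pool else off_pool
        peptide = source[int(rng.integers(len(source)))]
        spectrum = simulate_spectrum(peptide, cfg, rng, identifier=f"scan_{i}")
        spectra.append(spectrum)
        rows.append(
            {
                "spectrum_id": spectrum.identifier,
                "peptide": peptide.sequence,
                "charge": peptide.charge,
                "in_pool": from_pool,
            }
        )
    truth = pd.DataFrame(rows)
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return spectra, truth
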