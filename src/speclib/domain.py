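"""Core domain types: peaks, spectra, peptides, library entries, ion annotations.

All masses are monoisotopic Daltons; m/z values are Thomson. Residue indices
are 0-based internally and converted to 1-based only at the MSP boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .constants import (
    AMMONIA,
    CO,
    MODIFICATION_MASS,
    PROTON,
    RESIDUE_MASS,
    WATER,
)

#: Ion series understood by the engine. ``*_loss`` series are neutral-loss
#: satellites of their base series; ``internal`` fragments carry explicit
#: residue bounds instead of an ordinal.
ION_SERIES = (
    "b",
    "y",
    "a",
    "b_loss",
    "y_loss",
    "a_loss",
    "internal",
    "precursor_derived",
    "immonium",
)

NTERM = "nterm"
CTERM = "cterm"


@dataclass(frozen=True)
class IonAnnotation:
    """A fragment-ion assignment for one peak.

    ``ordinal`` counts residues from the series' terminus (1-based);
    ``internal_bounds`` is a 0-based half-open residue interval, present
    iff the series is ``internal``.
    """

    series: str
    ordinal: int = 0
    charge: int = 1
    neutral_loss: float = 0.0
    internal_bounds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.series not in ION_SERIES:
            raise ValueError(f"unknown ion series {self.series!r}")
        if (self.series == "internal") != (self.internal_bounds is not None):
            raise ValueError("internal_bounds present iff series is internal")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")

    @property
    def base_series(self) -> str:
        """The series letter ignoring neutral losses (y_loss -> y)."""
        return self.series.split("_")[0] if self.series != "internal" else "internal"

    def span(self, length: int) -> tuple[int, int]:
        """0-based half-open residue interval this ion covers in a peptide of
        ``length`` residues."""
        if self.series == "internal":
            return self.internal_bounds  # type: ignore[return-value]
        base = self.base_series
        if base in ("b", "a"):
            return (0, self.ordinal)
        if base == "y":
            return (length - self.ordinal, length)
        raise ValueError(f"series {self.series} has no residue span")


@dataclass
class Peak:
    mz: float
    intensity: float
    annotation: Optional[IonAnnotation] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A mass spectrum: precursor descriptor plus an m/z-sorted peak list."""

    identifier: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[Peak] = field(default_factory=list)
    normalized: bool = False
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.sort_peaks()

    def sort_peaks(self) -> None:
        self.peaks.sort(key=lambda p: p.mz)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def copy(self) -> "Spectrum":
        return Spectrum(
            identifier=self.identifier,
            precursor_mz=self.precursor_mz,
            precursor_charge=self.precursor_charge,
            peaks=[replace(p) for p in self.peaks],
            normalized=self.normalized,
            flagged_empty=self.flagged_empty,
        )


@dataclass(frozen=True)
class Modification:
    """A positioned mass delta. ``position`` is a 0-based residue index or
    one of the terminus tags ``"nterm"`` / ``"cterm"``."""

    position: int | str
    mass_delta: float
    name: str = ""


@dataclass
class Peptide:
    sequence: str
    modifications: list[Modification] = field(default_factory=list)
    charge: int = 2

    def __post_init__(self) -> None:
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise ValueError(f"unknown residue {aa!r} in {self.sequence!r}")
        for mod in self.modifications:
            if isinstance(mod.position, int) and not (
                0 <= mod.position < len(self.sequence)
            ):
                raise ValueError(
                    f"modification position {mod.position} outside sequence"
                )
            if isinstance(mod.position, str) and mod.position not in (NTERM, CTERM):
                raise ValueError(f"bad terminus tag {mod.position!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> list[float]:
        """Per-residue masses including positioned modification deltas
        (terminus mods excluded)."""
        masses = [RESIDUE_MASS[aa] for aa in self.sequence]
        for mod in self.modifications:
            if isinstance(mod.position, int):
                masses[mod.position] += mod.mass_delta
        return masses

    def terminal_delta(self, terminus: str) -> float:
        return sum(
            m.mass_delta for m in self.modifications if m.position == terminus
        )

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass of the (modified) peptide."""
        return (
            sum(self.residue_masses())
            + WATER
            + self.terminal_delta(NTERM)
            + self.terminal_delta(CTERM)
        )

    @property
    def precursor_mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge

    def fragment_mz(self, ann: IonAnnotation) -> float:
        """Theoretical m/z of the annotated fragment for this peptide."""
        return fragment_mz(self, ann)

    def stripped(self) -> str:
        return self.sequence


def fragment_mz(peptide: Peptide, ann: IonAnnotation) -> float:
    """Theoretical m/z of ``ann`` given ``peptide``.

    b ions are the N-terminal residue sum, y ions add water (they keep the
    C-terminal OH + H), a ions are b - CO, internal fragments are the bare
    residue sum of their interval (b-type second cleavage). Neutral losses
    subtract from the neutral fragment mass before protonation.
    """
    length = len(peptide.sequence)
    start, end = ann.span(length)
    if not (0 <= start < end <= length):
        raise ValueError(f"annotation span ({start},{end}) outside peptide")
    masses = peptide.residue_masses()
    neutral = math.fsum(masses[start:end])
    base = ann.base_series
    if base in ("b", "a"):
        neutral += peptide.terminal_delta(NTERM)
        if base == "a":
            neutral -= CO
    elif base == "y":
        neutral += WATER + peptide.terminal_delta(CTERM)
    elif base == "internal":
        if start == 0:
            neutral += peptide.terminal_delta(NTERM)
        if end == length:
            neutral += peptide.terminal_delta(CTERM)
    neutral -= ann.neutral_loss
    return (neutral + ann.charge * PROTON) / ann.charge


@dataclass
class LibraryEntry:
    """A peptide bound to its (possibly annotated) reference spectrum."""

    peptide: Peptide
    spectrum: Spectrum
    is_decoy: bool = False
    origin: str = ""
    comment_tokens: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.peptide.charge != self.spectrum.precursor_charge:
            raise ValueError(
                "precursor charge disagrees between peptide and spectrum"
            )

    def copy(self) -> "LibraryEntry":
        return LibraryEntry(
            peptide=Peptide(
                self.peptide.sequence,
                list(self.peptide.modifications),
                self.peptide.charge,
            ),
            spectrum=self.spectrum.copy(),
            is_decoy=self.is_decoy,
            origin=self.origin,
            comment_tokens=dict(self.comment_tokens),
        )


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    return 1e6 * (observed - theoretical) / theoretical
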