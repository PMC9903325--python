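"""Readers and writers for the text formats the engine touches.

MGF query runs are read through :mod:`pyteomics.mgf`. MSP spectral libraries
use the NIST text dialect (``Name: SEQ/charge``, ``Comment:`` key=value
tokens, ``Num peaks:`` and quoted peak annotations); no installed library
parses that peptide dialect with annotations, so it is implemented here.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd
from pyteomics import mgf as _mgf

from .constants import AMMONIA, MODIFICATION_MASS, WATER
from .domain import (
    CTERM,
    NTERM,
    IonAnnotation,
    LibraryEntry,
    Modification,
    Peak,
    Peptide,
    Spectrum,
    ppm_error,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_msp",
    "write_msp",
    "write_psm_table",
    "read_pool",
    "format_annotation",
    "parse_annotation",
]


class ParseError(ValueError):
    """Recoverable format error naming the offending block or entry."""


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of spectra, sorted peaks, one per block.

    Blocks without a PEPMASS line are skipped with a logged parse error
    naming the block; an empty file yields an empty list with a warning.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=0) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            title = str(params.get("title", "") or f"spectrum_{i}")
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.error("MGF block %r has no PEPMASS; skipped", title)
                continue
            charges = params.get("charge")
            charge = int(charges[0]) if charges else 1
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(block["m/z array"], block["intensity array"])
                if float(mz) > 0
            ]
            if not peaks:
                logger.error("MGF block %r has no peaks; skipped", title)
                continue
            spectra.append(
                Spectrum(
                    identifier=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
    if not spectra:
        logger.warning("MGF file %s contained no usable spectra", path)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF blocks (TITLE, PEPMASS, CHARGE, peak lines)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.4f} {p.intensity:.6g}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Ion annotation grammar: series ordinal [-loss] [^charge] [/err ppm]
# e.g.  y7   b3-H2O   y5-NH3^2   a2   Int3-6   Int3-6-H2O^2/1.2ppm

_ANNOT_RE = re.compile(
    r"^(?P<base>[aby])(?P<ordinal>\d+)"
    r"(?:-(?P<loss>H2O|NH3|\d+(?:\.\d+)?))?"
    r"(?:\^(?P<charge>\d+))?"
    r"(?:/(?P<err>[-+0-9.]+)ppm)?$"
)
_INTERNAL_RE = re.compile(
    r"^Int(?P<start>\d+)-(?P<end>\d+)"
    r"(?:-(?P<loss>H2O|NH3|\d+(?:\.\d+)?))?"
    r"(?:\^(?P<charge>\d+))?"
    r"(?:/(?P<err>[-+0-9.]+)ppm)?$"
)

_LOSS_NAME = {"H2O": WATER, "NH3": AMMONIA}


def _loss_token(loss: float) -> str:
    if abs(loss - WATER) < 1e-6:
        return "-H2O"
    if abs(loss - AMMONIA) < 1e-6:
        return "-NH3"
    return f"-{loss:.4f}"


def format_annotation(ann: IonAnnotation, err_ppm: Optional[float] = None) -> str:
    """Serialize an annotation to the MSP grammar. Internal bounds are
    written as a 1-based inclusive residue range (``Int3-6``)."""
    if ann.series == "internal":
        start, end = ann.internal_bounds  # type: ignore[misc]
        text = f"Int{start + 1}-{end}"
    else:
        text = f"{ann.base_series}{ann.ordinal}"
    if ann.neutral_loss:
        text += _loss_token(ann.neutral_loss)
    if ann.charge > 1:
        text += f"^{ann.charge}"
    if err_ppm is not None:
        text += f"/{err_ppm:.1f}ppm"
    return text


def parse_annotation(text: str) -> Optional[IonAnnotation]:
    """Parse an annotation string; returns None when outside the grammar."""
    text = text.strip().strip('"')
    m = _ANNOT_RE.match(text)
    if m:
        base = m.group("base")
        loss_tok = m.group("loss")
        loss = _LOSS_NAME.get(loss_tok, None) if loss_tok else 0.0
        if loss_tok and loss is None:
            loss = float(loss_tok)
        series = f"{base}_loss" if loss else base
        return IonAnnotation(
            series=series,
            ordinal=int(m.group("ordinal")),
            charge=int(m.group("charge") or 1),
            neutral_loss=loss or 0.0,
        )
    m = _INTERNAL_RE.match(text)
    if m:
        loss_tok = m.group("loss")
        loss = _LOSS_NAME.get(loss_tok, None) if loss_tok else 0.0
        if loss_tok and loss is None:
            loss = float(loss_tok)
        start = int(m.group("start")) - 1
        end = int(m.group("end"))
        if start < 0 or end <= start:
            return None
        return IonAnnotation(
            series="internal",
            charge=int(m.group("charge") or 1),
            neutral_loss=loss or 0.0,
            internal_bounds=(start, end),
        )
    return None


# ---------------------------------------------------------------------------
# MSP (NIST text dialect)

_MODS_ITEM_RE = re.compile(r"^(\d+|nterm|cterm),([A-Z\-]),?(.*)$")


def _format_mods(peptide: Peptide) -> str:
    if not peptide.modifications:
        return "Mods=0"
    items = []
    for mod in peptide.modifications:
        if isinstance(mod.position, int):
            pos = str(mod.position + 1)  # 1-based in MSP
            aa = peptide.sequence[mod.position]
        else:
            pos = mod.position
            aa = "-"
        items.append(f"{pos},{aa},{mod.name}")
    return f"Mods={len(items)}/" + "/".join(items)


def _parse_mods(token: str, sequence: str) -> list[Modification]:
    """Parse a ``k/pos,AA,Name`` Mods token (1-based positions)."""
    if token in ("0", ""):
        return []
    head, _, rest = token.partition("/")
    count = int(head)
    items = rest.split("/") if rest else []
    if len(items) != count:
        raise ParseError(f"Mods token count mismatch: {token!r}")
    mods: list[Modification] = []
    for item in items:
        m = _MODS_ITEM_RE.match(item)
        if not m:
            raise ParseError(f"unparseable Mods item {item!r}")
        pos_tok, aa, name = m.groups()
        position: int | str
        if pos_tok in (NTERM, CTERM):
            position = pos_tok
        else:
            position = int(pos_tok) - 1
            if not (0 <= position < len(sequence)):
                raise ParseError(f"Mods position {pos_tok} outside sequence")
        delta = MODIFICATION_MASS.get(name)
        if delta is None:
            logger.warning("unknown modification %r; mass delta set to 0", name)
            delta = 0.0
        mods.append(Modification(position, delta, name))
    return mods


def _comment_tokens(comment: str) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for part in comment.split():
        key, eq, value = part.partition("=")
        if eq:
            tokens[key] = value
    return tokens


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Read a NIST-style MSP library.

    Entries whose ``Num peaks`` disagrees with the actual peak count are
    skipped with a logged parse error; an unparseable ``Mods`` token keeps
    the entry with an empty modification list and a warning.
    """
    entries: list[LibraryEntry] = []
    with open(path) as fh:
        block: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("Name:") and block:
                _parse_msp_block(block, entries, path)
                block = []
            if line.strip() or block:
                block.append(line)
        if block:
            _parse_msp_block(block, entries, path)
    return entries


def _parse_msp_block(
    lines: list[str], entries: list[LibraryEntry], path: str | Path
) -> None:
    name = ""
    comment = ""
    num_peaks: Optional[int] = None
    precursor_mz: Optional[float] = None
    peak_lines: list[str] = []
    in_peaks = False
    for line in lines:
        if not line.strip():
            continue
        if in_peaks:
            peak_lines.append(line)
            continue
        key, _, value = line.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "name":
            name = value
        elif key == "comment":
            comment = value
        elif key in ("precursormz", "parentmz"):
            precursor_mz = float(value)
        elif key == "num peaks":
            num_peaks = int(value)
            in_peaks = True
    try:
        seq, _, charge_tok = name.partition("/")
        seq = seq.strip()
        charge = int(charge_tok) if charge_tok else 1
        if not seq:
            raise ParseError(f"MSP entry without Name in {path}")
        tokens = _comment_tokens(comment)
        if precursor_mz is None and "Parent" in tokens:
            precursor_mz = float(tokens["Parent"])
        try:
            mods = _parse_mods(tokens.get("Mods", "0"), seq)
        except ParseError as exc:
            logger.warning("entry %s: %s; modifications dropped", name, exc)
            mods = []
        peptide = Peptide(seq, mods, charge)
        if precursor_mz is None:
            precursor_mz = peptide.precursor_mz
        peaks: list[Peak] = []
        for pl in peak_lines:
            parts = pl.split(None, 2)
            if len(parts) < 2:
                continue
            ann = parse_annotation(parts[2]) if len(parts) > 2 else None
            peaks.append(Peak(float(parts[0]), float(parts[1]), ann))
        if num_peaks is not None and num_peaks != len(peaks):
            raise ParseError(
                f"entry {name}: Num peaks {num_peaks} != {len(peaks)} peak lines"
            )
        entries.append(
            LibraryEntry(
                peptide=peptide,
                spectrum=Spectrum(
                    identifier=name,
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    peaks=peaks,
                ),
                is_decoy=tokens.get("Decoy", "").lower() == "true",
                origin=tokens.get("Origin", str(path)),
                comment_tokens=tokens,
            )
        )
    except (ParseError, ValueError) as exc:
        logger.error("skipping MSP entry %r: %s", name, exc)


def write_msp(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write entries in the NIST text dialect; decoys carry ``Decoy=true``.

    Round-trips with :func:`read_msp` preserve sequences, charges, peak m/z
    to 4 decimals, intensities and annotations.
    """
    with open(path, "w") as fh:
        for entry in entries:
            pep = entry.peptide
            fh.write(f"Name: {pep.sequence}/{pep.charge}\n")
            fh.write(f"MW: {pep.neutral_mass:.6f}\n")
            tokens = [
                f"Parent={entry.spectrum.precursor_mz:.6f}",
                _format_mods(pep),
            ]
            if entry.is_decoy:
                tokens.append("Decoy=true")
            for key, value in sorted(entry.comment_tokens.items()):
                if key not in ("Parent", "Mods", "Decoy"):
                    tokens.append(f"{key}={value}")
            fh.write("Comment: " + " ".join(tokens) + "\n")
            fh.write(f"Num peaks: {len(entry.spectrum.peaks)}\n")
            for peak in entry.spectrum.peaks:
                line = f"{peak.mz:.4f}\t{peak.intensity:.6g}"
                if peak.annotation is not None:
                    err = ppm_error(peak.mz, pep.fragment_mz(peak.annotation))
                    line += f'\t"{format_annotation(peak.annotation, err)}"'
                fh.write(line + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Result tables and pool lists

#: Fixed ion-series column order of the PSM table.
PSM_SERIES_ORDER = ("y", "b", "a", "y_loss", "b_loss", "a_loss", "internal")


def write_psm_table(psms: Sequence, path: str | Path) -> pd.DataFrame:
    """Write PSMs as a TSV with scores, subscores and per-series matched
    intensities (absolute and relative); returns the DataFrame written."""
    rows = []
    for psm in psms:
        b = psm.breakdown
        row = {
            "spectrum_id": psm.spectrum_id,
            "peptide": psm.entry.peptide.sequence,
            "charge": psm.entry.peptide.charge,
            "is_decoy": psm.entry.is_decoy,
            "rank": psm.rank,
            "S": b.S,
            "P": b.P,
            "Q": b.Q,
            "p_B": b.p_B,
            "p_KT": b.p_KT,
            "p_HG": b.p_HG,
            "n_matched": b.n,
            "q_value": psm.q_value if psm.q_value is not None else "",
        }
        for series in PSM_SERIES_ORDER:
            absolute, relative = b.per_series.get(series, (0.0, 0.0))
            row[f"abs_{series}"] = absolute
            row[f"rel_{series}"] = relative
        rows.append(row)
    columns = (
        ["spectrum_id", "peptide", "charge", "is_decoy", "rank", "S", "P", "Q",
         "p_B", "p_KT", "p_HG", "n_matched", "q_value"]
        + [f"{kind}_{s}" for s in PSM_SERIES_ORDER for kind in ("abs", "rel")]
    )
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def read_pool(path: str | Path) -> list[str]:
    """Read a plain-text pool list: one uppercase sequence per line."""
    sequences = []
    with open(path) as fh:
        for line in fh:
            seq = line.strip().upper()
            if seq:
                sequences.append(seq)
    return sequences
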