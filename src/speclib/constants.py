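"""Physical constants and modification masses (monoisotopic, Da)."""

from pyteomics import mass as _pmass

PROTON = 1.00727646688
WATER = _pmass.calculate_mass(formula="H2O")  # 18.0105646...
AMMONIA = _pmass.calculate_mass(formula="NH3")  # 17.0265491...
CO = _pmass.calculate_mass(formula="CO")  # 27.9949146...

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

#: Built-in modification masses; the only ones the default searches use.
MODIFICATION_MASS: dict[str, float] = {
    "Carbamidomethyl": 57.02146,
    "Oxidation": 15.99491,
}

#: Residues able to lose water / ammonia as a fragment neutral loss.
H2O_LOSS_RESIDUES = frozenset("STED")
NH3_LOSS_RESIDUES = frozenset("KRNQ")
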