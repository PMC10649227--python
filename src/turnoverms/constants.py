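"""Frozen physical constants used throughout the package.

Elemental isotope masses and abundances are IUPAC 2013 representative
values, frozen here (rather than taken from a third-party table at run
time) so that isotope-pattern computations are bit-reproducible across
library upgrades.

The per-residue exchangeable-hydrogen counts are the Commerford-style
values conventionally used in heavy-water protein-turnover studies: the
average number of C-bound hydrogens per residue that equilibrate with
body-water deuterium during amino-acid biosynthesis in vivo.  They are
empirical averages, hence fractional.  Users with organism-specific
values can pass their own table to
:func:`turnoverms.isotope_model.count_exchangeable_hydrogens`.
"""

from __future__ import annotations

# (mass shift in nominal units, abundance) per element; index 0 is the
# lightest isotope.  Only elements occurring in unmodified peptides.
ELEMENT_ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017779, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088984, 0.00364)),
    "O": ((15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)),
    "S": ((31.97207069, 0.9499), (32.97145850, 0.0075),
          (33.96786683, 0.0425), (35.96708088, 0.0001)),
}

#: Natural deuterium abundance; the pH of the enrichment model.
NATURAL_DEUTERIUM = 0.000115

#: Mass difference between consecutive mass isotopomers (13C - 12C), Th at z=1.
ISOTOPE_SPACING = 1.003355

PROTON_MASS = 1.00727646688

# Elemental composition of amino-acid residues (in-chain, i.e. minus water).
RESIDUE_COMPOSITION: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Terminal groups of an unmodified linear peptide (H- ... -OH).
PEPTIDE_TERMINI: dict[str, int] = {"H": 2, "O": 1}

# Commerford-style average numbers of metabolically exchangeable
# (C-bound) hydrogens per residue.
EXCHANGEABLE_HYDROGENS: dict[str, float] = {
    "A": 4.00, "R": 3.43, "N": 1.89, "D": 1.89, "C": 1.62,
    "E": 3.95, "Q": 3.95, "G": 2.06, "H": 2.88, "I": 1.00,
    "L": 0.60, "K": 0.54, "M": 1.12, "F": 0.32, "P": 2.59,
    "S": 2.61, "T": 0.20, "W": 0.08, "Y": 0.42, "V": 0.56,
}
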